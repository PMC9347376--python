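"""Core data containers for the RP-UPLC capsid quantification workflow.

The pipeline operates on a small set of plain dataclasses: chromatogram
traces and integrated peaks, ESI mass spectra, calibration curves, and the
sample/instrument descriptions the synthetic-data generator consumes.
Validation happens in ``__post_init__`` so every downstream operation can
assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Average mass of one water molecule (Da), released/consumed in peptide-bond
#: chemistry. VP0 -> VP2 + VP4 maturation cleavage adds one water across the
#: scissile bond, so calc_mass(VP0) = calc_mass(VP2) + calc_mass(VP4) - H2O.
WATER_MASS = 18.015

#: Proton mass (Da) used for m/z <-> neutral-mass conversion in positive-mode ESI.
PROTON_MASS = 1.00728


@dataclass(frozen=True)
class VPDefinition:
    """One virion protein as the generator and the assigner see it.

    Parameters
    ----------
    name:
        One of ``VP0, VP1, VP2, VP3, VP4``.
    calc_mass:
        Average molecular mass in Da (sequence-calculated).
    trp_count:
        Tryptophan content used as the fluorescence response proxy; the FLR
        channel (Ex 280 / Em 352 nm) is dominated by Trp emission. May be
        fractional to model a weak residual response (e.g. Tyr) for proteins
        with no tryptophan.
    ref_rt:
        Reference retention time in minutes.
    peak_sigma:
        Gaussian peak standard deviation in minutes.
    """

    name: str
    calc_mass: float
    trp_count: float
    ref_rt: float
    peak_sigma: float

    def __post_init__(self) -> None:
        if self.name not in {"VP0", "VP1", "VP2", "VP3", "VP4"}:
            raise ValueError(f"unknown virion protein name: {self.name!r}")
        if self.calc_mass <= 0:
            raise ValueError("calc_mass must be positive")
        if self.trp_count < 0:
            raise ValueError("trp_count must be >= 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")


def check_cleavage_consistency(vps: dict[str, VPDefinition], tol: float = 1.0) -> float:
    """Verify that VP0 mass equals VP2 + VP4 minus one water.

    Maturation cleaves VP0 into VP2 and VP4 without losing residues, so the
    three average masses must close to within ``tol`` Da once the hydrolytic
    water is accounted for. Returns the residual (VP0 - (VP2 + VP4 - H2O)).
    """
    resid = vps["VP0"].calc_mass - (
        vps["VP2"].calc_mass + vps["VP4"].calc_mass - WATER_MASS
    )
    if abs(resid) > tol:
        raise ValueError(
            f"VP0/VP2+VP4 mass closure violated: residual {resid:+.2f} Da > {tol} Da"
        )
    return resid


@dataclass(frozen=True)
class CapsidModel:
    """Stoichiometry of empty procapsids and full mature virions.

    Empty procapsids carry 60 copies each of VP0, VP1, VP3; full virions
    carry 60 copies each of VP1, VP2, VP3, VP4 (VP0 is cleaved to VP2 + VP4
    after RNA encapsidation). Because cleavage conserves residues, the total
    fluorescence response per capsid is identical for both forms.
    """

    copies_per_capsid: int = 60
    empty_composition: tuple[str, ...] = ("VP0", "VP1", "VP3")
    full_composition: tuple[str, ...] = ("VP1", "VP2", "VP3", "VP4")

    def __post_init__(self) -> None:
        if self.copies_per_capsid <= 0:
            raise ValueError("copies_per_capsid must be positive")

    def occupancy(self, vp_name: str, empty_fraction: float) -> float:
        """Fraction of capsids in which ``vp_name`` is present.

        VP0 occurs only in empty capsids; VP2/VP4 only in full capsids;
        VP1/VP3 in both.
        """
        in_empty = vp_name in self.empty_composition
        in_full = vp_name in self.full_composition
        return empty_fraction * in_empty + (1.0 - empty_fraction) * in_full

    def check_response_balance(self, vps: dict[str, VPDefinition], tol: float = 1e-9) -> None:
        """Assert empty and full compositions have equal total Trp response."""
        empty = sum(vps[n].trp_count for n in self.empty_composition)
        full = sum(vps[n].trp_count for n in self.full_composition)
        if abs(empty - full) > tol:
            raise ValueError(
                f"Trp response not conserved across cleavage: empty {empty} vs full {full}"
            )


@dataclass(frozen=True)
class SampleSpec:
    """A virus sample as loaded on the autosampler."""

    capsid_conc: float  # capsids/mL
    empty_fraction: float  # in [0, 1]
    dilution_factor: float = 1.0
    injection_volume: float = 0.010  # mL

    def __post_init__(self) -> None:
        if self.capsid_conc < 0:
            raise ValueError("capsid_conc must be >= 0")
        if not 0.0 <= self.empty_fraction <= 1.0:
            raise ValueError("empty_fraction must be in [0, 1]")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.injection_volume <= 0:
            raise ValueError("injection_volume must be positive")

    @property
    def injected_capsids(self) -> float:
        """Capsids loaded per injection: conc x volume / dilution."""
        return self.capsid_conc * self.injection_volume / self.dilution_factor


@dataclass(frozen=True)
class InstrumentSpec:
    """Detector/acquisition parameters for the synthetic FLR channel."""

    sampling_rate: float = 600.0  # points/min
    run_time: float = 11.5  # minutes
    noise_sd: float = 5.0e4  # additive white noise, signal units
    baseline_drift: float = 0.0  # signal units per minute
    response_per_trp: float = 2.25e-6  # area units per (capsid copy x Trp)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.run_time <= 0:
            raise ValueError("run_time must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Trace:
    """A sampled detector signal over time for one channel."""

    time: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray
    channel: str = "FLR"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time vector must be strictly increasing")
        if steps.max() / steps.min() >= 1.5:
            raise ValueError("trace sampling is too non-uniform (max/min step >= 1.5)")

    @property
    def dt(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.time)))


@dataclass
class Peak:
    """An integrated chromatographic feature."""

    rt: float  # apex, minutes
    area: float  # detector units x min
    height: float
    fwhm: float  # minutes
    start: float
    end: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.rt < self.end:
            raise ValueError(f"apex {self.rt} outside bounds [{self.start}, {self.end}]")
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass(frozen=True)
class ResolutionResult:
    """Chromatographic resolution between a pair of labeled peaks."""

    pair: tuple[str, str]
    rs: float

    def __post_init__(self) -> None:
        if self.rs < 0:
            raise ValueError("resolution must be >= 0")

    @property
    def passes_regulatory(self) -> bool:
        """True when Rs exceeds the Rs > 2 validation requirement."""
        return self.rs > 2.0


@dataclass
class Spectrum:
    """A mass spectrum: m/z vs intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def is_empty(self) -> bool:
        return self.mz.size == 0 or not np.any(self.intensity > 0)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration of total VP peak area vs particles per injection."""

    slope: float  # area per capsid
    intercept: float  # area
    r2: float
    range: tuple[float, float]  # [min, max] capsids/injection

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must be in [0, 1]")

    def in_range(self, particles: float) -> bool:
        lo, hi = self.range
        return lo <= particles <= hi


@dataclass
class QuantResult:
    """Per-sample quantification output: capsid count, concentration, ratio."""

    capsids_per_injection: float
    capsid_conc: float  # capsids/mL
    ef_ratio: float  # VP0/(VP2+VP4) area ratio
    ef_ratio_simplified: float  # VP0/VP2
    empty_fraction: float
    per_vp_areas: dict[str, float]
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.ef_ratio < 0:
            raise ValueError("ef_ratio must be >= 0")
        if not 0.0 <= self.empty_fraction <= 1.0:
            raise ValueError("empty_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """A volumetric mixture of characterized samples (spike-accuracy design)."""

    components: tuple[tuple[SampleSpec, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        fractions = [f for _, f in self.components]
        if any(not 0.0 < f <= 1.0 for f in fractions):
            raise ValueError("volume fractions must be in (0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")


@dataclass(frozen=True)
class ProteinSpecies:
    """A candidate protein for mass assignment, by sequence or fixed mass."""

    name: str
    mass: float  # average Da
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass(frozen=True)
class Adduct:
    """A neutral mass shift observed on intact proteins.

    ``Myr`` is N-terminal myristoylation (+210.36 Da average, C14 acyl);
    ``Na`` is an H->Na replacement (+21.98 Da) on the neutral deconvoluted
    mass.
    """

    name: str
    delta: float  # Da
    max_count: int = 1

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError("max_count must be >= 0")


@dataclass(frozen=True)
class MassAssignment:
    """A deconvoluted mass matched to a species plus an adduct multiset."""

    observed: float
    species: ProteinSpecies | None  # None = no match within tolerance
    adducts: tuple[tuple[str, int], ...]  # ((name, count), ...)
    residual: float  # observed - species.mass - sum(count * delta)

    @property
    def matched(self) -> bool:
        return self.species is not None

    @property
    def label(self) -> str:
        """Human-readable assignment, e.g. ``VP0+Myr+Na``."""
        if self.species is None:
            return "no-match"
        parts = [self.species.name]
        for name, count in self.adducts:
            if count == 1:
                parts.append(name)
            elif count > 1:
                parts.append(f"{count}{name}")
        return "+".join(parts)
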