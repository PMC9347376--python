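"""Seeded synthetic chromatograms and ESI spectra with known ground truth.

The generator encodes the structural model the assay exploits:

* every capsid carries 60 copies of each constituent VP — empty procapsids
  have VP0/VP1/VP3, full virions VP1/VP2/VP3/VP4;
* fluorescence response is proportional to tryptophan content, and Trp is
  conserved across the maturation cleavage VP0 -> VP2 + VP4, so the total
  FLR area per capsid is independent of the empty fraction;
* ESI of an intact protein of mass M produces a ladder of peaks at
  (M + z * m_p) / z across a symmetric charge-state envelope.

Ground truth (per-VP areas, injected particle number) is returned alongside
every trace so tests can score detection and quantification against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import (
    PROTON_MASS,
    CapsidModel,
    InstrumentSpec,
    SampleSpec,
    Spectrum,
    Trace,
    VPDefinition,
)
from .reference import MZ_WINDOW

__all__ = [
    "ChromatogramTruth",
    "simulate_chromatogram",
    "simulate_standard_series",
    "simulate_esi_spectrum",
]


@dataclass
class ChromatogramTruth:
    """Ground truth attached to a simulated chromatogram."""

    injected_capsids: float
    areas: dict[str, float]  # per-VP true areas (pre-noise)
    rts: dict[str, float]
    sample: SampleSpec
    warnings: list[str] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))


def _gaussian(t: np.ndarray, rt: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2)


def _emg(t: np.ndarray, rt: float, sigma: float, area: float, tau: float) -> np.ndarray:
    """Exponentially modified Gaussian with unit-area normalization."""
    from scipy.stats import exponnorm

    k = tau / sigma
    return area * exponnorm.pdf(t, k, loc=rt, scale=sigma)


def true_peak_area(
    sample: SampleSpec, vp: VPDefinition, capsid: CapsidModel, inst: InstrumentSpec
) -> float:
    """Closed-form expected FLR area for one VP.

    area = injected_capsids x copies_per_capsid x occupancy(vp)
           x trp_count(vp) x response_per_trp

    where occupancy is the fraction of capsids containing the VP
    (empty_fraction for VP0; 1 - empty_fraction for VP2/VP4; 1 for VP1/VP3).
    """
    occ = capsid.occupancy(vp.name, sample.empty_fraction)
    return (
        sample.injected_capsids
        * capsid.copies_per_capsid
        * occ
        * vp.trp_count
        * inst.response_per_trp
    )


def simulate_chromatogram(
    sample: SampleSpec,
    vps: list[VPDefinition] | dict[str, VPDefinition],
    capsid: CapsidModel | None = None,
    inst: InstrumentSpec | None = None,
    *,
    rng: np.random.Generator | None = None,
    peak_shape: str = "gaussian",
    emg_tau: float = 0.02,
) -> tuple[Trace, ChromatogramTruth]:
    """Simulate one FLR chromatogram of a capsid sample.

    The trace is baseline drift + white Gaussian noise + one Gaussian peak
    per VP whose area follows the capsid stoichiometry / Trp response model.
    ``peak_shape='emg'`` switches to an exponentially modified Gaussian with
    time constant ``emg_tau`` (minutes) for tailing-robustness studies.

    Returns the trace and a :class:`ChromatogramTruth` sidecar with the
    noise-free per-VP areas.
    """
    capsid = capsid or CapsidModel()
    inst = inst or InstrumentSpec()
    if isinstance(vps, dict):
        vps = list(vps.values())
    for vp in vps:
        if not 0.0 <= vp.ref_rt <= inst.run_time:
            raise ValueError(
                f"{vp.name} ref_rt {vp.ref_rt} min outside run time {inst.run_time} min"
            )
    rng = rng if rng is not None else np.random.default_rng(inst.seed)

    n = int(round(inst.run_time * inst.sampling_rate)) + 1
    t = np.linspace(0.0, inst.run_time, n)
    signal = inst.baseline_drift * t + rng.normal(0.0, inst.noise_sd, size=n)

    truth_warnings: list[str] = []
    ordered = sorted(vps, key=lambda v: v.ref_rt)
    for a, b in zip(ordered, ordered[1:]):
        if b.ref_rt - a.ref_rt < 3.0 * max(a.peak_sigma, b.peak_sigma):
            msg = f"peaks {a.name}/{b.name} closer than 3 sigma ({a.ref_rt}/{b.ref_rt} min)"
            truth_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    areas: dict[str, float] = {}
    rts: dict[str, float] = {}
    for vp in vps:
        area = true_peak_area(sample, vp, capsid, inst)
        areas[vp.name] = area
        rts[vp.name] = vp.ref_rt
        if area > 0:
            if peak_shape == "gaussian":
                signal += _gaussian(t, vp.ref_rt, vp.peak_sigma, area)
            elif peak_shape == "emg":
                signal += _emg(t, vp.ref_rt, vp.peak_sigma, area, emg_tau)
            else:
                raise ValueError(f"unknown peak_shape: {peak_shape!r}")

    trace = Trace(time=t, signal=signal, channel="FLR")
    truth = ChromatogramTruth(
        injected_capsids=sample.injected_capsids,
        areas=areas,
        rts=rts,
        sample=sample,
        warnings=truth_warnings,
    )
    return trace, truth


def simulate_standard_series(
    levels: list[float],
    vps: list[VPDefinition] | dict[str, VPDefinition],
    capsid: CapsidModel | None = None,
    inst: InstrumentSpec | None = None,
    *,
    empty_fraction: float = 0.0025,
    injection_volume: float = 0.010,
    area_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[Trace, ChromatogramTruth]]:
    """Simulate a calibration series at the given particles-per-injection levels.

    Each level becomes one seeded chromatogram whose noise-free total area is
    exactly proportional to the level. ``area_cv`` adds multiplicative
    injection-to-injection area noise (relative SD, e.g. 0.01 for 1%) by
    scaling the effective injected amount — this models volumetric/loading
    variability on top of the detector noise in ``inst``.

    The default ``empty_fraction`` mirrors a typical purified standard
    (~0.25% empty capsids); the total-area response is independent of it.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("standard series needs at least one level")
    if any(lv <= 0 for lv in levels):
        raise ValueError("standard levels must be strictly positive")
    capsid = capsid or CapsidModel()
    inst = inst or InstrumentSpec()
    rng = rng if rng is not None else np.random.default_rng(inst.seed)

    out = []
    for level in levels:
        scale = 1.0
        if area_cv > 0:
            scale = max(rng.normal(1.0, area_cv), 0.0)
        sample = SampleSpec(
            capsid_conc=level * scale / injection_volume,
            empty_fraction=empty_fraction,
            dilution_factor=1.0,
            injection_volume=injection_volume,
        )
        trace, truth = simulate_chromatogram(sample, vps, capsid, inst, rng=rng)
        out.append((trace, truth))
    return out


def expected_standard_slope(
    vps: list[VPDefinition] | dict[str, VPDefinition],
    capsid: CapsidModel | None = None,
    inst: InstrumentSpec | None = None,
) -> float:
    """Closed-form slope of total area vs particles per injection.

    slope = response_per_trp x copies_per_capsid x (total Trp per capsid),
    independent of empty fraction because Trp is conserved across cleavage
    (the empty and full compositions respond identically).
    """
    capsid = capsid or CapsidModel()
    inst = inst or InstrumentSpec()
    if isinstance(vps, dict):
        vps = list(vps.values())
    trp = {v.name: v.trp_count for v in vps}
    total_trp = sum(trp[n] for n in capsid.full_composition)
    return inst.response_per_trp * capsid.copies_per_capsid * total_trp


def simulate_esi_spectrum(
    masses: list[float],
    charge_range: tuple[int, int],
    inst: InstrumentSpec | None = None,
    *,
    mz_window: tuple[float, float] = MZ_WINDOW,
    mz_step: float = 0.1,
    fwhm: float = 0.8,
    intensities: list[float] | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Simulate a positive-mode ESI spectrum of intact proteins.

    For each neutral mass M and each charge z in ``charge_range``, a Gaussian
    peak of half-height width ``fwhm`` (m/z units; instrument default 0.8,
    alternative 1.0) is placed at (M + z * 1.00728) / z. Peaks falling outside
    ``mz_window`` are silently dropped. Charge-state intensities follow a
    symmetric (Gaussian) envelope centered on the middle of the charge range.
    """
    if any(m <= 0 for m in masses):
        raise ValueError("masses must be positive")
    zmin, zmax = charge_range
    if zmax < zmin or zmin < 1:
        raise ValueError("charge_range must be a nonempty positive interval")
    inst = inst or InstrumentSpec()
    rng = rng if rng is not None else np.random.default_rng(inst.seed)

    lo, hi = mz_window
    mz = np.arange(lo, hi + mz_step / 2, mz_step)
    intensity = np.zeros_like(mz)
    if noise_sd > 0:
        intensity += np.abs(rng.normal(0.0, noise_sd, size=mz.size))

    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    charges = np.arange(zmin, zmax + 1)
    z_mid = 0.5 * (zmin + zmax)
    z_sd = max((zmax - zmin) / 4.0, 0.5)
    envelope = np.exp(-0.5 * ((charges - z_mid) / z_sd) ** 2)

    if intensities is None:
        intensities = [1.0] * len(masses)
    for m, base in zip(masses, intensities):
        for z, env in zip(charges, envelope):
            center = (m + z * PROTON_MASS) / z
            if not lo <= center <= hi:
                continue
            intensity += base * env * np.exp(-0.5 * ((mz - center) / sigma) ** 2)

    return Spectrum(mz=mz, intensity=intensity)
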