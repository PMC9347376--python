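"""Capsid quantification: calibration, concentration, and empty/full ratio.

The assay's central structure: cleavage of VP0 into VP2 + VP4 conserves
residues, so (i) total VP peak area tracks total capsid count regardless of
the empty/full composition, and (ii) the VP0/(VP2+VP4) area ratio equals the
empty:full particle ratio. Capsid number per injection comes from a linear
standard curve,

    capsids/injection = (total VP area - intercept) / slope,

and concentration from

    capsids/mL = capsids_per_injection / (injection_volume / dilution_factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .chromatogram import rsd
from .models import MixtureSpec, Peak, QuantResult, StandardCurve

__all__ = [
    "fit_standard_curve",
    "capsids_per_injection",
    "capsid_concentration",
    "empty_full_ratio",
    "empty_fraction",
    "quantify_sample",
    "dilutional_linearity",
    "theoretical_mixture",
    "accuracy_percent",
    "process_flag",
]


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of total VP area vs particles per injection.

    Unweighted, with a free intercept. Requires >= 3 points with distinct
    particle levels. The validated range is [min x, max x].
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standard levels must not all coincide")
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=min(float(fit.rvalue**2), 1.0),
        range=(float(x.min()), float(x.max())),
    )


class CapsidCount(NamedTuple):
    """Back-calculated particles per injection, with range flag."""

    value: float
    extrapolated: bool


def capsids_per_injection(total_area: float, curve: StandardCurve) -> CapsidCount:
    """Invert the standard curve: (area - intercept) / slope.

    A result outside the validated curve range is returned with
    ``extrapolated=True``; a negative result raises, naming the inputs.
    """
    n = (total_area - curve.intercept) / curve.slope
    if n < 0:
        raise ValueError(
            f"negative capsid count: area {total_area:.4g} below intercept "
            f"{curve.intercept:.4g} (slope {curve.slope:.4g})"
        )
    return CapsidCount(value=float(n), extrapolated=not curve.in_range(n))


def capsid_concentration(
    n: float, injection_volume: float, dilution_factor: float = 1.0
) -> float:
    """Capsids/mL = capsids_per_injection / (injection_volume / dilution)."""
    if injection_volume <= 0:
        raise ValueError("injection_volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return n / (injection_volume / dilution_factor)


def empty_full_ratio(
    per_vp_areas: dict[str, float],
    simplified: bool = False,
    response_correction: dict[str, float] | None = None,
) -> float:
    """Empty/full capsid ratio from FLR areas: VP0/(VP2+VP4).

    ``simplified=True`` returns VP0/VP2, the quick process-monitoring form
    (VP4 has no tryptophan, so its FLR contribution is <1% of VP2's).
    Missing VP0 means no detectable empty capsids (ratio 0); a missing VP4
    area contributes 0 to the denominator. ``response_correction`` optionally
    rescales each area by a per-VP factor before the ratio (defaults to
    identity — areas are comparable as-is because Trp is conserved across
    the VP0 cleavage).
    """
    corr = response_correction or {}

    def a(name: str, default: float | None = None) -> float:
        v = per_vp_areas.get(name, default)
        if v is None:
            raise ValueError(f"missing {name} peak area")
        return v * corr.get(name, 1.0)

    vp0 = a("VP0", default=0.0)
    if simplified:
        denom = a("VP2")
    else:
        denom = a("VP2") + a("VP4", default=0.0)
    if denom <= 0:
        raise ValueError("no full capsids detectable: VP2(+VP4) area is zero")
    return vp0 / denom


def empty_fraction(ratio: float) -> float:
    """Convert the empty/full ratio r to the empty-capsid fraction r/(1+r)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ratio / (1.0 + ratio)


def quantify_sample(
    per_vp_areas: dict[str, float] | dict[str, Peak | None],
    curve: StandardCurve,
    injection_volume: float = 0.010,
    dilution_factor: float = 1.0,
) -> QuantResult:
    """End-to-end quantification of one injection from per-VP areas.

    Accepts either raw areas or the peak map from
    :func:`~vpquant.chromatogram.assign_peaks` (absent VPs count as area 0).
    """
    areas: dict[str, float] = {}
    for name, v in per_vp_areas.items():
        if v is None:
            areas[name] = 0.0
        elif isinstance(v, Peak):
            areas[name] = v.area
        else:
            areas[name] = float(v)

    total = sum(areas.values())
    count = capsids_per_injection(total, curve)
    conc = capsid_concentration(count.value, injection_volume, dilution_factor)
    ratio = empty_full_ratio(areas)
    simplified = empty_full_ratio(areas, simplified=True)
    return QuantResult(
        capsids_per_injection=count.value,
        capsid_conc=conc,
        ef_ratio=ratio,
        ef_ratio_simplified=simplified,
        empty_fraction=empty_fraction(ratio),
        per_vp_areas=areas,
        extrapolated=count.extrapolated,
    )


@dataclass(frozen=True)
class DilutionalLinearity:
    """Dilutional-linearity report: regression quality and conc agreement."""

    r2: float
    slope: float  # capsids per mL of corrected injected volume
    conc_rsd: float  # %RSD of back-calculated concentration across levels
    n_levels: int


def dilutional_linearity(
    results: list[tuple[float, float, float]],
    injection_volume: float = 0.010,
) -> DilutionalLinearity:
    """Assess serial-dilution consistency of one sample.

    ``results`` holds (dilution_factor, capsids_per_injection, capsid_conc)
    per level — e.g. neat, 1.5x, 3x, 6x, 15x. The particle number per
    injection is regressed against the corrected injected volume
    (injection_volume / dilution_factor); the %RSD of the back-calculated
    concentration measures cross-level agreement. Duplicate dilution levels
    are averaged with a warning.
    """
    if len(results) < 3:
        raise ValueError("dilutional linearity needs at least 3 levels")
    by_level: dict[float, list[tuple[float, float]]] = {}
    for d, n, c in results:
        by_level.setdefault(d, []).append((n, c))
    if len(by_level) < len(results):
        warnings.warn("duplicate dilution levels collapsed by averaging", stacklevel=2)
    levels = sorted(by_level)
    vol = np.array([injection_volume / d for d in levels])
    n_inj = np.array([np.mean([v[0] for v in by_level[d]]) for d in levels])
    concs = np.array([np.mean([v[1] for v in by_level[d]]) for d in levels])

    fit = stats.linregress(vol, n_inj)
    return DilutionalLinearity(
        r2=min(float(fit.rvalue**2), 1.0),
        slope=float(fit.slope),
        conc_rsd=rsd(concs),
        n_levels=len(levels),
    )


class MixtureTheoretical(NamedTuple):
    """Expected composition of a volumetric mixture of known samples."""

    capsid_conc: float
    empty_fraction: float
    ef_ratio: float


def theoretical_mixture(mix: MixtureSpec) -> MixtureTheoretical:
    """Expected concentration and empty/full ratio of a spike mixture.

    Concentration is volume-weighted; the empty fraction is weighted by
    capsid count (v_i * C_i), not volume — each component contributes empty
    particles in proportion to the particles it brings, so only
    capsid-weighted averaging balances the particle bookkeeping.
    """
    total_capsids = sum(v * s.capsid_conc for s, v in mix.components)
    if total_capsids <= 0:
        raise ValueError("mixture has no capsids")
    total_empty = sum(v * s.capsid_conc * s.empty_fraction for s, v in mix.components)
    f = total_empty / total_capsids
    ratio = f / (1.0 - f) if f < 1.0 else float("inf")
    return MixtureTheoretical(
        capsid_conc=float(total_capsids), empty_fraction=float(f), ef_ratio=float(ratio)
    )


def accuracy_percent(
    measured: float, theoretical: float, rounded: bool = True
) -> float:
    """Spike recovery: 100 x measured / theoretical (integer for reports)."""
    if theoretical == 0:
        raise ValueError("theoretical value must be nonzero")
    pct = 100.0 * measured / theoretical
    return float(round(pct)) if rounded else pct


def process_flag(ef_ratio_simplified: float, threshold: float) -> str:
    """Flag a purification sample whose VP0/VP2 ratio exceeds ``threshold``.

    Typical thresholds: 0.04 for purification intermediates, 0.01 for drug
    substance. Returns ``"flag"`` (undesired empty-capsid content) or
    ``"pass"``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "flag" if ef_ratio_simplified > threshold else "pass"
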