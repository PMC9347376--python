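"""Intact-mass identification of virion proteins from ESI spectra.

Three stages: average-mass computation from sequence, charge-state
deconvolution of the multiply-charged m/z spectrum into neutral masses, and
combinatorial assignment of each observed mass to a candidate protein plus
an adduct multiset (myristoylation, sodium).

The deconvolution is a transparent charge-ladder scorer: each candidate
neutral mass M predicts an m/z ladder (M + z * m_p)/z over the charge
range, and is scored by the geometric mean of (Gaussian-smoothed) spectrum
intensity at *adjacent* charge states, weighted by the fraction of charge
states with real support. Requiring consecutive-charge evidence suppresses
harmonic artifacts — a 2M ghost matches only every second rung of the true
ladder, so each of its adjacent pairs contains an empty rung. Local maxima
of the score over the mass grid, refined by parabolic interpolation, are
the deconvoluted masses.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from pyteomics import mass as pymass
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .models import PROTON_MASS, Adduct, MassAssignment, ProteinSpecies, Spectrum
from .reference import DEFAULT_ADDUCTS, DEFAULT_MASS_TOL

__all__ = [
    "average_mass",
    "deconvolute",
    "assign_mass",
    "mass_delta_table",
]

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def average_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a protein sequence.

    Sum of residue average masses plus one water; the empty sequence returns
    the water mass. Raises on characters outside the 20 standard residues.
    """
    bad = set(sequence) - _STANDARD_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    if not sequence:
        return float(pymass.calculate_mass(composition=pymass.Composition("H2O"), average=True))
    return float(pymass.calculate_mass(sequence=sequence, average=True))


def deconvolute(
    spec: Spectrum,
    mass_grid: tuple[float, float, float],
    charges: tuple[int, int],
    *,
    fwhm: float = 0.8,
    rel_threshold: float = 0.2,
    support_frac: float = 0.01,
) -> list[tuple[float, float]]:
    """Charge-state deconvolution of an ESI spectrum to neutral masses.

    Parameters
    ----------
    spec:
        The m/z spectrum (profile or centroided-on-a-grid).
    mass_grid:
        (min, max, step) of candidate neutral masses in Da; default step
        0.5 Da is adequate for average masses of 7-40 kDa proteins.
    charges:
        Inclusive charge range (zmin, zmax) to sum over.
    fwhm:
        Half-height width (m/z) of the Gaussian kernel applied to the
        spectrum before ladder lookup; matches the instrument peak model
        (default 0.8, alternative 1.0).
    rel_threshold:
        Keep local score maxima above this fraction of the global maximum.
    support_frac:
        A charge state "supports" a candidate when its ladder intensity
        exceeds this fraction of the spectrum maximum; scores are weighted
        by the supported fraction of the charge range.

    Returns ``(mass, score)`` pairs sorted by descending score.
    """
    lo, hi, step = mass_grid
    if step <= 0:
        raise ValueError("mass grid step must be positive")
    if hi <= lo:
        raise ValueError("mass grid must be a nonempty interval")
    zmin, zmax = charges
    if zmax < zmin or zmin < 1:
        raise ValueError("charge range must be a nonempty positive interval")
    if spec.is_empty:
        return []

    mz, inten = spec.mz, spec.intensity
    if fwhm > 0 and mz.size > 1:
        mz_step = float(np.median(np.diff(mz)))
        sigma_pts = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / mz_step
        inten = gaussian_filter1d(inten, sigma_pts)

    masses = np.arange(lo, hi + step / 2, step)
    support_level = support_frac * float(inten.max())
    n_charges = zmax - zmin + 1
    rungs = np.zeros((n_charges, masses.size))
    for k, z in enumerate(range(zmin, zmax + 1)):
        ladder = (masses + z * PROTON_MASS) / z
        inside = (ladder >= mz[0]) & (ladder <= mz[-1])
        rungs[k, inside] = np.interp(ladder[inside], mz, inten)
    support = (rungs > support_level).sum(axis=0)
    if n_charges > 1:
        # Adjacent-charge geometric mean: both rungs of each pair must exist.
        score = np.sqrt(rungs[:-1] * rungs[1:]).sum(axis=0)
    else:
        score = rungs[0].copy()
    score *= support / n_charges

    if not np.any(score > 0):
        return []
    peak_idx, _ = sps.find_peaks(score, height=rel_threshold * float(score.max()))
    out = []
    for i in peak_idx:
        # Parabolic refinement on the score surface.
        if 0 < i < score.size - 1:
            y0, y1, y2 = score[i - 1], score[i], score[i + 1]
            denom = y0 - 2.0 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -1.0, 1.0))
        else:
            delta = 0.0
        out.append((float(masses[i] + delta * step), float(score[i])))
    out.sort(key=lambda p: -p[1])
    return out


def _enumerate_adducts(adducts: list[Adduct]):
    """All adduct multisets up to each adduct's max_count, as count tuples."""
    ranges = [range(a.max_count + 1) for a in adducts]
    yield from product(*ranges)


def assign_mass(
    observed: float,
    candidates: list[ProteinSpecies],
    adducts: list[Adduct] | tuple[Adduct, ...] = DEFAULT_ADDUCTS,
    tol: float = DEFAULT_MASS_TOL,
) -> MassAssignment:
    """Assign an observed neutral mass to a protein plus adduct multiset.

    Exhaustive search over candidates x adduct count vectors (by default
    Myr <= 1, Na <= 3); the assignment minimizing (|residual|, total adduct
    count) lexicographically wins. If nothing lands within ``tol`` Da, a
    no-match result (``species=None``) is returned rather than raising.
    """
    if not candidates:
        raise ValueError("candidate species list must be nonempty")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    adducts = list(adducts)

    best: tuple[float, int, ProteinSpecies, tuple[int, ...]] | None = None
    for species in candidates:
        for counts in _enumerate_adducts(adducts):
            shift = sum(c * a.delta for c, a in zip(counts, adducts))
            resid = observed - species.mass - shift
            key = (abs(resid), sum(counts))
            if abs(resid) <= tol and (best is None or key < (best[0], best[1])):
                best = (abs(resid), sum(counts), species, counts)

    if best is None:
        return MassAssignment(observed=observed, species=None, adducts=(), residual=float("nan"))
    _, _, species, counts = best
    shift = sum(c * a.delta for c, a in zip(counts, adducts))
    pairs = tuple((a.name, c) for a, c in zip(adducts, counts) if c > 0)
    return MassAssignment(
        observed=observed,
        species=species,
        adducts=pairs,
        residual=float(observed - species.mass - shift),
    )


def mass_delta_table(
    calculated: dict[str, float], observed: dict[str, float]
) -> dict[str, int | None]:
    """Observed minus calculated mass per protein, as integers.

    Proteins present in only one of the inputs appear with ``None`` (a gap
    in the table) rather than raising.
    """
    names = list(calculated) + [n for n in observed if n not in calculated]
    return {
        name: (
            int(round(observed[name] - calculated[name]))
            if name in calculated and name in observed
            else None
        )
        for name in names
    }
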