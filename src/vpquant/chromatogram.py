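"""Peak detection, integration, assignment, and chromatographic statistics.

Replaces the vendor integration software in the workflow: peaks are found by
prominence against a robust noise estimate, bounded at flanking signal
minima, integrated trapezoidally above a drop-line baseline, and matched to
virion proteins by retention time.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps

from .models import Peak, ResolutionResult, Trace

__all__ = [
    "detect_peaks",
    "integrate_peak",
    "resolution",
    "assign_peaks",
    "rsd",
    "robust_noise",
]

log = logging.getLogger(__name__)

#: Rs at half-height: Rs = 1.18 (t2 - t1) / (w_h1 + w_h2), the EP convention.
_RS_HALF_HEIGHT = 1.18
#: Tangent width of a Gaussian is 1.699x its half-height width.
_TANGENT_PER_FWHM = 1.699


def robust_noise(signal: np.ndarray) -> float:
    """Noise SD estimate from the median absolute successive difference.

    For white noise, median(|x[i+1] - x[i]|) = sd * sqrt(2) * 0.6745...;
    peaks contribute little because successive differences of a smooth peak
    are small relative to its height.
    """
    d = np.diff(signal)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * 0.674489750196082))


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex (rt, height) via parabola through the 3 points around sample i."""
    if i == 0 or i == y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(t[i] + delta * dt), float(height)


def detect_peaks(
    trace: Trace,
    min_prominence: float = 10.0,
    min_fwhm: float = 0.01,
    baseline_mode: str = "drop_line",
) -> list[Peak]:
    """Detect and integrate peaks in a trace.

    Parameters
    ----------
    trace:
        The chromatogram. The time axis must be strictly increasing (the
        :class:`~vpquant.models.Trace` constructor enforces this).
    min_prominence:
        Prominence threshold as a multiple of the robust noise estimate.
    min_fwhm:
        Minimum half-height width in minutes; narrower features are treated
        as spikes and dropped.
    baseline_mode:
        Baseline model passed through to :func:`integrate_peak`.

    Returns peaks sorted by retention time, with apexes refined by parabolic
    interpolation and bounds at the flanking signal minima.
    """
    t, y = trace.time, trace.signal
    noise = robust_noise(y)
    # Floor keeps noiseless synthetic traces from flagging numerical ripple.
    floor = 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    prominence = max(min_prominence * noise, floor)

    idx, props = sps.find_peaks(y, prominence=prominence)
    if idx.size == 0:
        return []

    dt = trace.dt
    widths, _, _, _ = sps.peak_widths(y, idx, rel_height=0.5)

    # Bounds: minimum of the signal between adjacent apexes (trace edges for
    # the outermost peaks), i.e. valley positions.
    bounds_idx = []
    for k, i in enumerate(idx):
        left_lim = idx[k - 1] if k > 0 else 0
        right_lim = idx[k + 1] if k < idx.size - 1 else y.size - 1
        li = left_lim + int(np.argmin(y[left_lim : i + 1])) if i > left_lim else left_lim
        ri = i + int(np.argmin(y[i : right_lim + 1])) if right_lim > i else right_lim
        bounds_idx.append((li, ri))

    peaks: list[Peak] = []
    for i, w, (li, ri) in zip(idx, widths, bounds_idx):
        fwhm = float(w * dt)
        if fwhm < min_fwhm:
            continue
        rt, height = _parabolic_apex(t, y, i)
        start, end = float(t[li]), float(t[ri])
        if not start < rt < end:
            continue
        area = integrate_peak(trace, (start, end), baseline_mode=baseline_mode)
        baseline_at_apex = 0.5 * (y[li] + y[ri])
        peaks.append(
            Peak(
                rt=rt,
                area=area,
                height=float(height - baseline_at_apex),
                fwhm=fwhm,
                start=start,
                end=end,
            )
        )
    peaks.sort(key=lambda p: p.rt)
    return peaks


def integrate_peak(
    trace: Trace,
    bounds: tuple[float, float],
    baseline_mode: str = "drop_line",
) -> float:
    """Trapezoidal area of the baseline-subtracted signal inside ``bounds``.

    ``drop_line`` anchors the baseline on robust (median-of-5) signal levels
    at each bound, which resists a noisy sample landing exactly on the
    bound; ``valley_to_valley`` uses the raw signal values at the bounds.
    A negative net area is clipped to 0 with a warning.
    """
    start, end = bounds
    if start >= end:
        raise ValueError("integration window is empty")
    t, y = trace.time, trace.signal
    if start < t[0] - 1e-12 or end > t[-1] + 1e-12:
        raise ValueError("integration bounds outside trace span")
    mask = (t >= start) & (t <= end)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than two samples")
    tw, yw = t[mask], y[mask]

    if baseline_mode == "valley_to_valley":
        b0, b1 = yw[0], yw[-1]
    elif baseline_mode == "drop_line":
        k = min(5, yw.size)
        b0 = float(np.median(yw[:k]))
        b1 = float(np.median(yw[-k:]))
    else:
        raise ValueError(f"unknown baseline_mode: {baseline_mode!r}")

    baseline = b0 + (b1 - b0) * (tw - tw[0]) / (tw[-1] - tw[0])
    area = float(np.trapezoid(yw - baseline, tw))
    if area < 0:
        warnings.warn(
            f"negative integrated area {area:.3g} clipped to 0 in [{start}, {end}]",
            stacklevel=2,
        )
        area = 0.0
    return area


def resolution(p1: Peak, p2: Peak, method: str = "half_height") -> ResolutionResult:
    """Chromatographic resolution between two peaks (p1 elutes first).

    ``half_height``: Rs = 1.18 (t2 - t1) / (w_h1 + w_h2) — the European
    Pharmacopoeia convention on half-height widths. ``tangent``: the USP
    baseline-width form Rs = 2 (t2 - t1) / (w_b1 + w_b2), with tangent
    widths derived from the half-height widths assuming Gaussian shape.
    """
    if p1.rt > p2.rt:
        raise ValueError("p1 must elute before p2")
    if p1.fwhm <= 0 or p2.fwhm <= 0:
        raise ValueError("peak widths must be positive")
    dt = p2.rt - p1.rt
    if method == "half_height":
        rs = _RS_HALF_HEIGHT * dt / (p1.fwhm + p2.fwhm)
    elif method == "tangent":
        rs = 2.0 * dt / (_TANGENT_PER_FWHM * (p1.fwhm + p2.fwhm))
    else:
        raise ValueError(f"unknown resolution method: {method!r}")
    return ResolutionResult(
        pair=(p1.label or "peak1", p2.label or "peak2"), rs=float(rs)
    )


def assign_peaks(
    peaks: list[Peak],
    refs: dict[str, float],
    tol: float = 0.3,
) -> dict[str, Peak | None]:
    """Label peaks with VP names by nearest reference retention time.

    Each VP takes the nearest unassigned peak within ``tol`` minutes.
    When two VPs contend for one peak, the smaller |Δrt| wins, then the
    larger peak area; the collision is logged. A VP with no peak within
    tolerance maps to ``None`` (e.g. VP0 is absent from purified full
    capsids). Peak ``label`` fields are set in place on matched peaks.
    """
    if not refs:
        raise ValueError("reference retention times must be nonempty")
    assigned: dict[str, Peak | None] = {name: None for name in refs}
    if not peaks:
        return assigned

    # Candidate (vp, peak) pairs within tolerance, best matches first.
    candidates = []
    for name, ref_rt in refs.items():
        for p in peaks:
            drt = abs(p.rt - ref_rt)
            if drt <= tol:
                candidates.append((drt, -p.area, name, p))
    candidates.sort(key=lambda c: (c[0], c[1]))

    taken: set[int] = set()
    for drt, _, name, p in candidates:
        if assigned[name] is not None:
            continue
        if id(p) in taken:
            log.info(
                "peak at %.3f min contested; %s deferred (|drt|=%.3f)", p.rt, name, drt
            )
            continue
        assigned[name] = p
        p.label = name
        taken.add(id(p))
    return assigned


def rsd(values) -> float:
    """Percent relative standard deviation: 100 x sample SD (n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("%RSD needs at least two values")
    mean = float(np.mean(x))
    if mean == 0:
        raise ValueError("%RSD undefined for zero mean")
    return float(100.0 * np.std(x, ddof=1) / mean)
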