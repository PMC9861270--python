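"""Stabilization trimming, artifact detection and cubic-spline correction.

Resting HRV protocols discard the first minute of each recording as a
stabilization period.  The remaining beats are screened for artifacts and
ectopic beats with a threshold rule — an interval deviating more than
0.25 s from the reference mean is abnormal — and flagged beats are
replaced by a cubic spline fitted over the clean beats in cumulative time.
A recording is accepted for analysis only when fewer than 20% of its beats
required correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import CorrectionImpossibleError, ValidationError
from .rr_io import RRSeries

__all__ = [
    "CorrectionReport",
    "trim_stabilization",
    "detect_artifacts",
    "correct_artifacts",
    "clean_series",
    "ACCEPTANCE_FRACTION",
]

#: Strict upper bound on the corrected-beat fraction for an accepted recording.
ACCEPTANCE_FRACTION = 0.20

#: Default artifact threshold: deviation from the reference mean, in seconds.
DEFAULT_THRESHOLD_S = 0.25


@dataclass(frozen=True)
class CorrectionReport:
    """Outcome of artifact correction on one recording.

    ``corrected`` has the same length as ``original``; beats not listed in
    ``flagged_indices`` are bit-identical in both.  ``accepted`` is true
    iff ``fraction_corrected`` is strictly below 20%.
    """

    original: RRSeries
    corrected: RRSeries
    flagged_indices: tuple
    n_corrected: int
    fraction_corrected: float
    accepted: bool
    warnings: tuple = ()


def trim_stabilization(series: RRSeries, trim_seconds: float = 60.0) -> RRSeries:
    """Drop the stabilization period at the start of a recording.

    A beat is retained iff its start time (the cumulative sum of all
    preceding intervals) is at or beyond the trim boundary; a beat
    straddling the boundary is excluded.
    """
    if trim_seconds < 0:
        raise ValidationError("trim_seconds must be non-negative")
    if series.duration_s <= trim_seconds:
        raise ValidationError(
            f"recording lasts {series.duration_s:.1f} s, cannot trim {trim_seconds:.1f} s"
        )
    keep = series.start_times_ms >= trim_seconds * 1000.0
    return series.replace(intervals=series.intervals[keep])


def detect_artifacts(
    series: RRSeries,
    threshold_seconds: float = DEFAULT_THRESHOLD_S,
    reference: Literal["global_mean", "local_mean"] = "global_mean",
    local_window: int = 11,
) -> tuple:
    """Flag beats deviating more than ``threshold_seconds`` from a mean.

    Under ``global_mean`` (the default) the reference is the mean of the
    whole recording and detection is one-shot.  Under ``local_mean`` the
    reference for beat *i* is the mean of its not-yet-flagged neighbours
    within a centred window of ``local_window`` beats, computed in a
    single left-to-right pass.

    Returns the flagged beat indices as a sorted tuple.
    """
    if len(series) < 3:
        raise ValidationError("artifact detection requires at least 3 beats")
    if threshold_seconds <= 0:
        raise ValidationError("threshold_seconds must be positive")
    thr_ms = threshold_seconds * 1000.0
    rr = series.intervals

    if reference == "global_mean":
        dev = np.abs(rr - rr.mean())
        return tuple(int(i) for i in np.nonzero(dev > thr_ms)[0])

    if reference != "local_mean":
        raise ValidationError(f"unknown reference {reference!r}")
    if local_window < 3:
        raise ValidationError("local_window must be at least 3 beats")
    half = local_window // 2
    flagged: list[int] = []
    flagged_mask = np.zeros(len(rr), dtype=bool)
    global_mean = rr.mean()
    for i in range(len(rr)):
        lo, hi = max(0, i - half), min(len(rr), i + half + 1)
        neighbours = [rr[j] for j in range(lo, hi) if j != i and not flagged_mask[j]]
        ref = float(np.mean(neighbours)) if neighbours else global_mean
        if abs(rr[i] - ref) > thr_ms:
            flagged.append(i)
            flagged_mask[i] = True
    return tuple(flagged)


def correct_artifacts(series: RRSeries, flagged: Sequence[int]) -> CorrectionReport:
    """Replace flagged beats by cubic-spline interpolation in cumulative time.

    The spline is fitted to (cumulative time, RR) over the unflagged beats
    and evaluated at each flagged beat's original cumulative time, so
    unequal beat spacing is respected.  Flagged beats outside the span of
    the clean beats (no bracketing support) fall back to the nearest clean
    value and are recorded in ``warnings``.
    """
    n = len(series)
    flagged = sorted(set(int(i) for i in flagged))
    if flagged and (flagged[0] < 0 or flagged[-1] >= n):
        raise ValidationError("flagged index out of range")

    if not flagged:
        return CorrectionReport(
            original=series,
            corrected=series.replace(intervals=series.intervals.copy()),
            flagged_indices=(),
            n_corrected=0,
            fraction_corrected=0.0,
            accepted=True,
        )

    mask = np.zeros(n, dtype=bool)
    mask[flagged] = True
    n_clean = int((~mask).sum())
    if n_clean < 4:
        raise CorrectionImpossibleError(
            f"cubic-spline correction needs at least 4 clean beats, have {n_clean}"
        )

    t = series.cumulative_ms
    t_clean, rr_clean = t[~mask], series.intervals[~mask]
    spline = CubicSpline(t_clean, rr_clean)

    corrected = series.intervals.copy()
    warns: list[str] = []
    for i in flagged:
        ti = t[i]
        if t_clean[0] <= ti <= t_clean[-1]:
            corrected[i] = float(spline(ti))
        else:
            j = int(np.argmin(np.abs(t_clean - ti)))
            corrected[i] = rr_clean[j]
            warns.append(f"beat {i}: no bracketing clean beats, nearest-neighbour fallback")
    if np.any(corrected <= 0):
        raise CorrectionImpossibleError("spline replacement produced a non-positive interval")

    fraction = len(flagged) / n
    return CorrectionReport(
        original=series,
        corrected=series.replace(intervals=corrected),
        flagged_indices=tuple(flagged),
        n_corrected=len(flagged),
        fraction_corrected=fraction,
        accepted=fraction < ACCEPTANCE_FRACTION,
        warnings=tuple(warns),
    )


def clean_series(
    series: RRSeries,
    threshold_seconds: float = DEFAULT_THRESHOLD_S,
    reference: Literal["global_mean", "local_mean"] = "global_mean",
    local_window: int = 11,
) -> CorrectionReport:
    """Detect and correct artifacts in one step (detection then spline)."""
    flagged = detect_artifacts(series, threshold_seconds, reference, local_window)
    return correct_artifacts(series, flagged)
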