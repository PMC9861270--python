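"""Time-domain HRV: rMSSD, LnrMSSD and mean heart rate over analysis windows.

rMSSD — the root mean square of successive RR-interval differences — is
the time-domain index of parasympathetic activity best suited to short
and ultra-short recordings.  Because rMSSD is right-skewed across
subjects, group statistics are computed on its natural logarithm
(LnrMSSD, of the millisecond value).  A standard resting measurement uses
a 5-minute window; the ultra-short variant uses the first minute of the
same segment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .rr_io import RRSeries

__all__ = [
    "AnalysisWindow",
    "HRVResult",
    "ULTRA_SHORT_S",
    "SHORT_S",
    "rmssd",
    "ln_rmssd",
    "extract_window",
    "hrv_result",
    "analyze_recording",
]

ULTRA_SHORT_S = 60.0
SHORT_S = 300.0


@dataclass(frozen=True)
class AnalysisWindow:
    """A half-open time window [start, start + duration) in seconds."""

    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration <= 0:
            raise ValidationError("window requires start >= 0 and duration > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class HRVResult:
    """Time-domain HRV summary for one analysis window.

    ``ln_rmssd`` is None when rMSSD is zero (a constant series has no
    log value); use :func:`ln_rmssd` directly when an error is preferred.
    """

    rmssd: float
    ln_rmssd: Optional[float]
    mean_rr: float
    mean_hr: float
    n_beats: int
    window: AnalysisWindow


def rmssd(intervals: Sequence[float]) -> float:
    """Root mean square of successive differences, in milliseconds."""
    arr = np.asarray(intervals, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("rMSSD requires at least 2 intervals")
    diffs = np.diff(arr)
    return float(np.sqrt(np.mean(diffs * diffs)))


def ln_rmssd(rmssd_ms: float) -> float:
    """Natural log of an rMSSD value expressed in milliseconds."""
    if rmssd_ms <= 0:
        raise UndefinedStatisticError(
            f"LnrMSSD is undefined for rMSSD = {rmssd_ms!r} ms (constant series?)"
        )
    return math.log(rmssd_ms)


def extract_window(series: RRSeries, window: AnalysisWindow) -> RRSeries:
    """Beats whose start time falls in the half-open window.

    The window must fit within the recording's total duration.
    """
    if window.end > series.duration_s + 1e-9:
        raise ValidationError(
            f"window [{window.start}, {window.end}) s exceeds recording "
            f"duration {series.duration_s:.1f} s"
        )
    starts = series.start_times_ms
    keep = (starts >= window.start * 1000.0) & (starts < window.end * 1000.0)
    if not keep.any():
        raise ValidationError("window contains no beats")
    return series.replace(intervals=series.intervals[keep])


def hrv_result(series: RRSeries, window: AnalysisWindow) -> HRVResult:
    """Compute the HRV summary for one window of a recording."""
    segment = extract_window(series, window)
    value = rmssd(segment.intervals)
    mean_rr = float(segment.intervals.mean())
    return HRVResult(
        rmssd=value,
        ln_rmssd=math.log(value) if value > 0 else None,
        mean_rr=mean_rr,
        mean_hr=60000.0 / mean_rr,
        n_beats=len(segment),
        window=window,
    )


def analyze_recording(series: RRSeries) -> tuple[HRVResult, HRVResult]:
    """Ultra-short (first minute) and short (full 5 min) HRV of a segment.

    ``series`` must already have its stabilization minute trimmed and
    last at least 300 s.  The ultra-short window is the FIRST minute of
    the analysis segment.
    """
    if series.duration_s < SHORT_S:
        raise ValidationError(
            f"analysis segment lasts {series.duration_s:.1f} s; 300 s required"
        )
    ultra = hrv_result(series, AnalysisWindow(0.0, ULTRA_SHORT_S))
    short = hrv_result(series, AnalysisWindow(0.0, SHORT_S))
    return ultra, short
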