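"""Reading and writing RR-interval recordings and daily HRV histories.

The native dialect is deliberately minimal: one RR interval per line, in
milliseconds, optionally preceded by header lines of the form
``# key=value`` carrying recording metadata (subject, device, position,
trial, free-text origin).  A CSV alternative is sniffed by the presence of
a comma on the first line; it must carry an ``rr_ms`` column and may carry
per-file metadata columns.

Values are stored in milliseconds throughout.  A file whose values are all
below 10 almost certainly holds seconds; such files are loaded verbatim but
emit :class:`UnitWarning` and set :attr:`RRSeries.unit_suspect` — there is
never a silent unit conversion.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "Device",
    "Position",
    "RRSeries",
    "DailyHRVRecord",
    "UnitWarning",
    "read_rr_text",
    "write_rr_text",
    "read_daily_history",
    "write_daily_history",
]


class UnitWarning(UserWarning):
    """Raised when a file's values look like seconds rather than ms."""


class Device(str, enum.Enum):
    ECG = "ecg"
    APP = "app"
    OTHER = "other"


class Position(str, enum.Enum):
    SUPINE = "supine"
    SEATED = "seated"
    UNKNOWN = "unknown"


@dataclass
class RRSeries:
    """A beat-to-beat interval recording with acquisition metadata.

    Parameters
    ----------
    intervals
        RR intervals in milliseconds, one per beat, in recording order.
        Every interval must be strictly positive and finite.
    subject_id
        Opaque subject identifier.
    device
        Acquisition route: ``ecg`` (gold standard), ``app`` (chest-strap
        fed smartphone analysis) or ``other``.
    position
        Body position during recording.
    sample_origin
        Free-text provenance note.
    extra
        Additional ``key=value`` metadata round-tripped through files
        (e.g. ``trial``).
    """

    intervals: np.ndarray
    subject_id: str = ""
    device: Device = Device.OTHER
    position: Position = Position.UNKNOWN
    sample_origin: str = ""
    extra: dict = field(default_factory=dict)
    unit_suspect: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("RRSeries requires a non-empty 1-D interval sequence")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("RR intervals must be finite")
        if np.any(arr <= 0):
            bad = int(np.argmax(arr <= 0))
            raise ValidationError(f"RR interval at beat {bad} is non-positive ({arr[bad]!r} ms)")
        self.intervals = arr
        self.device = Device(self.device)
        self.position = Position(self.position)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def n_beats(self) -> int:
        return len(self)

    @property
    def duration_ms(self) -> float:
        """Total recording duration: the running sum of all intervals."""
        return float(self.intervals.sum())

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def cumulative_ms(self) -> np.ndarray:
        """Cumulative time at the END of each beat (running sum)."""
        return np.cumsum(self.intervals)

    @property
    def start_times_ms(self) -> np.ndarray:
        """Cumulative time at the START of each beat (exclusive prefix sum)."""
        return self.cumulative_ms - self.intervals

    def replace(self, **changes) -> "RRSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DailyHRVRecord:
    """One day's LnrMSSD measurement in a daily-monitoring history."""

    date: _dt.date
    ln_rmssd: float
    flags: frozenset = frozenset()

    @property
    def rejected(self) -> bool:
        return "rejected" in self.flags


_META_KEYS = {"subject", "subject_id", "device", "position", "origin", "sample_origin"}


def _series_from_metadata(values: Sequence[float], meta: dict, path) -> RRSeries:
    extra = {k: v for k, v in meta.items() if k not in _META_KEYS}
    arr = np.asarray(values, dtype=float)
    suspect = bool(arr.size and np.all(arr < 10))
    if suspect:
        warnings.warn(
            f"{path}: all RR values are < 10; file likely holds seconds, "
            "loaded verbatim as milliseconds (no conversion applied)",
            UnitWarning,
            stacklevel=3,
        )
    series = RRSeries(
        intervals=arr,
        subject_id=str(meta.get("subject_id", meta.get("subject", ""))),
        device=Device(meta.get("device", "other")),
        position=Position(meta.get("position", "unknown")),
        sample_origin=str(meta.get("sample_origin", meta.get("origin", ""))),
        extra=extra,
    )
    series.unit_suspect = suspect
    return series


def _read_rr_csv(path: Path) -> RRSeries:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    if "rr_ms" in frame.columns:
        col = frame["rr_ms"]
    elif frame.shape[1] == 1:
        col = frame.iloc[:, 0]
    else:
        raise ParseError(f"{path}: CSV dialect requires an 'rr_ms' column")
    values = pd.to_numeric(col, errors="coerce")
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-numeric RR value at line {line}")
    meta = {}
    for key in ("subject_id", "device", "position", "sample_origin", "trial"):
        if key in frame.columns and len(frame):
            meta[key] = str(frame[key].iloc[0])
    return _series_from_metadata(values.to_numpy(dtype=float), meta, path)


def read_rr_text(path) -> RRSeries:
    """Read an RR-interval recording from the line or CSV dialect.

    Raises
    ------
    ParseError
        On a non-numeric token (the message names the line).
    ValidationError
        On a non-positive interval or an empty file.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise ValidationError(f"{path}: file is empty")
    first = next(line for line in lines if line.strip())
    if "," in first:
        return _read_rr_csv(path)

    meta: dict = {}
    values: list[float] = []
    value_lines: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        try:
            value = float(line)
        except ValueError:
            raise ParseError(f"{path}: non-numeric token {line!r} at line {lineno}") from None
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(
                f"{path}: non-positive RR interval {value!r} at line {lineno}"
            )
        values.append(value)
        value_lines.append(lineno)
    if not values:
        raise ValidationError(f"{path}: no RR values found")
    return _series_from_metadata(values, meta, path)


def write_rr_text(series: RRSeries, path) -> Path:
    """Write ``series`` in the line dialect; round-trips exactly.

    Metadata is emitted as one ``# key=value`` header line per field, and
    interval values use shortest round-trip float formatting, so
    ``read_rr_text(write_rr_text(s))`` reproduces ``s`` bit for bit.
    """
    if not isinstance(series, RRSeries):
        raise ValidationError("write_rr_text expects an RRSeries")
    path = Path(path)
    lines = []
    if series.subject_id:
        lines.append(f"# subject_id={series.subject_id}")
    if series.device is not Device.OTHER:
        lines.append(f"# device={series.device.value}")
    if series.position is not Position.UNKNOWN:
        lines.append(f"# position={series.position.value}")
    if series.sample_origin:
        lines.append(f"# sample_origin={series.sample_origin}")
    for key, val in series.extra.items():
        lines.append(f"# {key}={val}")
    lines.extend(repr(float(v)) for v in series.intervals)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_daily_history(path) -> list[DailyHRVRecord]:
    """Read a daily LnrMSSD history CSV (columns ``date``, ``ln_rmssd``).

    Records are returned sorted ascending by date; duplicate dates are a
    validation error.  An optional ``flags`` column holds ';'-separated
    tags (e.g. ``rejected``).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    missing = {"date", "ln_rmssd"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        dates = pd.to_datetime(frame["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable date: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate date {dup}")
    records = []
    for date, ln, flags in zip(
        dates,
        pd.to_numeric(frame["ln_rmssd"]),
        frame.get("flags", pd.Series([""] * len(frame))).fillna(""),
    ):
        tags = frozenset(t for t in str(flags).split(";") if t)
        records.append(DailyHRVRecord(date=date, ln_rmssd=float(ln), flags=tags))
    records.sort(key=lambda r: r.date)
    return records


def write_daily_history(records: Iterable[DailyHRVRecord], path) -> Path:
    path = Path(path)
    rows = [
        {"date": r.date.isoformat(), "ln_rmssd": r.ln_rmssd, "flags": ";".join(sorted(r.flags))}
        for r in records
    ]
    pd.DataFrame(rows, columns=["date", "ln_rmssd", "flags"]).to_csv(path, index=False)
    return path
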