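"""HRV-guided day-to-day training prescription.

The engine mirrors the decision logic of HRV-guided training programmes:
a one-month control period of daily LnrMSSD measurements defines a
normative zone — the smallest worthwhile change, SWC = mean ± 0.5 × SD.
During the programme the trailing 7-day rolling average of LnrMSSD is
compared against the SWC on each scheduled training day:

* the first training day is always low intensity;
* rolling average inside the SWC → high-intensity session;
* rolling average outside the SWC → low intensity on the first such day,
  rest while the deviation persists (escalating recovery);
* a single day back inside the SWC resets the escalation.

Progression is gamified: completing a session (high or low) earns a star;
reaching the star threshold advances the level (four levels, four
sessions each, saturating at level 4).  The default schedule is three
sessions per week for twelve weeks.
"""
from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .rr_io import DailyHRVRecord

__all__ = [
    "Intensity",
    "BaselineProfile",
    "TrainingState",
    "TrainingDecision",
    "TrainingConfig",
    "DegenerateBaselineWarning",
    "build_baseline",
    "rolling_7day",
    "decide_session",
    "update_progression",
    "run_programme",
]


class DegenerateBaselineWarning(UserWarning):
    """The baseline SD is zero: the SWC collapses to a point."""


class Intensity(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    REST = "rest"


@dataclass(frozen=True)
class BaselineProfile:
    """Normative LnrMSSD profile from the control month."""

    mean_ln: float
    sd_ln: float
    swc_lower: float
    swc_upper: float
    n_days: int

    def contains(self, value: float) -> bool:
        return self.swc_lower <= value <= self.swc_upper


@dataclass
class TrainingState:
    """Mutable programme state threaded through consecutive decisions."""

    day_index: int = 0
    last_decision: Optional[Intensity] = None
    consecutive_outside: int = 0
    level: int = 1
    stars: int = 0
    sessions_completed: int = 0
    history: list = field(default_factory=list)


@dataclass(frozen=True)
class TrainingDecision:
    """One scheduled training day's prescription."""

    intensity: Intensity
    session_id: Optional[int]
    rolling_avg: Optional[float]
    in_swc: bool
    level: int
    date: Optional[_dt.date] = None
    warnings: tuple = ()


@dataclass(frozen=True)
class TrainingConfig:
    """Schedule and progression parameters with their conventional defaults."""

    swc_multiplier: float = 0.5
    rolling_window_days: int = 7
    training_weekdays: tuple = (0, 2, 4)  # Mon/Wed/Fri
    programme_weeks: int = 12
    levels: int = 4
    sessions_per_level: int = 4
    stars_per_level: int = 9
    baseline_min_days: int = 21
    #: "low_then_rest": first outside day low, consecutive outside days rest.
    #: "always_low": never escalate to rest.
    escalation_policy: str = "low_then_rest"

    def __post_init__(self) -> None:
        if len(self.training_weekdays) != len(set(self.training_weekdays)):
            raise ValidationError("training_weekdays must be distinct")
        if self.escalation_policy not in ("low_then_rest", "always_low"):
            raise ValidationError(f"unknown escalation policy {self.escalation_policy!r}")


def build_baseline(
    history: Sequence[DailyHRVRecord],
    min_days: int = 21,
    swc_multiplier: float = 0.5,
) -> BaselineProfile:
    """Profile the control period: mean, SD and SWC bounds of LnrMSSD.

    Records flagged ``rejected`` are excluded.  A zero SD collapses the
    SWC to a point and emits :class:`DegenerateBaselineWarning` (every
    subsequent day will fall "outside").
    """
    values = np.array([r.ln_rmssd for r in history if not r.rejected], dtype=float)
    if values.size < min_days:
        raise InsufficientDataError(
            f"baseline needs at least {min_days} usable days, have {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "baseline SD is zero: SWC collapses to a point", DegenerateBaselineWarning
        )
    return BaselineProfile(
        mean_ln=mean,
        sd_ln=sd,
        swc_lower=mean - swc_multiplier * sd,
        swc_upper=mean + swc_multiplier * sd,
        n_days=int(values.size),
    )


def rolling_7day(
    history: Sequence[DailyHRVRecord],
    today: _dt.date,
    window_days: int = 7,
) -> float:
    """Trailing rolling average of LnrMSSD over the window ending today.

    The mean is taken over the records actually present in the window
    (missing days are simply absent); an empty window is an error.
    """
    start = today - _dt.timedelta(days=window_days - 1)
    values = [
        r.ln_rmssd for r in history if start <= r.date <= today and not r.rejected
    ]
    if not values:
        raise InsufficientDataError(f"no usable records in the {window_days}-day window ending {today}")
    return float(np.mean(values))


def decide_session(
    profile: BaselineProfile,
    state: TrainingState,
    rolling: Optional[float],
    config: TrainingConfig = TrainingConfig(),
    date: Optional[_dt.date] = None,
) -> TrainingDecision:
    """Prescribe today's session intensity and advance the state.

    The first training day is low intensity regardless of the rolling
    value (and does not count toward escalation).  Thereafter a rolling
    average inside the SWC prescribes high intensity and resets the
    outside-streak; outside the SWC the escalation policy applies.  A
    missing rolling value defers the decision to rest with a warning.
    """
    state.day_index += 1
    warns: list[str] = []

    if rolling is None:
        intensity, in_swc = Intensity.REST, False
        warns.append("no rolling LnrMSSD available: decision deferred to rest")
    else:
        in_swc = profile.contains(rolling)
        if state.day_index == 1:
            intensity = Intensity.LOW
        elif in_swc:
            intensity = Intensity.HIGH
            state.consecutive_outside = 0
        else:
            if config.escalation_policy == "always_low" or state.consecutive_outside == 0:
                intensity = Intensity.LOW
            else:
                intensity = Intensity.REST
            state.consecutive_outside += 1

    session_id = (
        state.sessions_completed % config.sessions_per_level + 1
        if intensity is not Intensity.REST
        else None
    )
    state.last_decision = intensity
    return TrainingDecision(
        intensity=intensity,
        session_id=session_id,
        rolling_avg=rolling,
        in_swc=in_swc,
        level=state.level,
        date=date,
        warnings=tuple(warns),
    )


def update_progression(
    state: TrainingState,
    completed: TrainingDecision,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingState:
    """Award a star for a completed session and handle level progression.

    Rest days award nothing.  On reaching the star threshold the level
    increments and stars reset; at the top level the progression
    saturates (level stays 4, stars cap at the threshold).
    """
    if completed.intensity is Intensity.REST:
        return state
    state.sessions_completed += 1
    state.stars += 1
    if state.stars >= config.stars_per_level:
        if state.level < config.levels:
            state.level += 1
            state.stars = 0
        else:
            state.stars = config.stars_per_level
    return state


def _scheduled_dates(start: _dt.date, config: TrainingConfig) -> list[_dt.date]:
    # First scheduled day is the first configured weekday on/after `start`;
    # the horizon is programme_weeks * sessions-per-week decisions.
    n_target = config.programme_weeks * len(config.training_weekdays)
    dates = []
    day = start
    while len(dates) < n_target:
        if day.weekday() in config.training_weekdays:
            dates.append(day)
        day += _dt.timedelta(days=1)
    return dates


def run_programme(
    profile: BaselineProfile,
    daily_hrv: Iterable[DailyHRVRecord],
    config: TrainingConfig = TrainingConfig(),
    start_date: Optional[_dt.date] = None,
) -> list[TrainingDecision]:
    """Run the full programme over a daily LnrMSSD stream.

    One decision is produced per scheduled training day (default Mon/Wed/
    Fri over 12 weeks: 36 decisions), threading the state through
    :func:`decide_session` and :func:`update_progression`.  If the record
    stream ends before the horizon (no usable record in a scheduled day's
    rolling window and none later), the output is truncated with a
    warning.
    """
    records = sorted(daily_hrv, key=lambda r: r.date)
    if not records:
        raise InsufficientDataError("daily HRV stream is empty")
    if start_date is None:
        start_date = records[0].date
    last_record = max(r.date for r in records)

    state = TrainingState()
    decisions: list[TrainingDecision] = []
    for date in _scheduled_dates(start_date, config):
        try:
            rolling = rolling_7day(records, date, config.rolling_window_days)
        except InsufficientDataError:
            if date > last_record:
                warnings.warn(
                    f"daily HRV stream ends {last_record}; programme truncated at "
                    f"{len(decisions)} decisions"
                )
                break
            rolling = None
        decision = decide_session(profile, state, rolling, config, date)
        state = update_progression(state, decision, config)
        state.history.append(decision)
        decisions.append(decision)
    return decisions
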