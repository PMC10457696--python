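"""Core data model for CGM dawn-phenomenon analysis.

The unit of observation is the *participant-day*: a continuous-glucose-monitor
(CGM) trace sliced to one calendar date, together with that day's meal diary.
Day-level scoring produces :class:`DayMetrics`, which every downstream module
(thresholds, opportunity counting, mixed models) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, time as Time, timedelta
from typing import Iterable

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# small time helpers

def time_to_hours(t: Time) -> float:
    """Clock time -> decimal hours (08:30 -> 8.5)."""
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def time_to_minutes(t: Time) -> float:
    """Clock time -> exact minutes since midnight (no float round-trip)."""
    return t.hour * 60 + t.minute + t.second / 60.0


def hours_to_time(h: float) -> Time:
    """Decimal hours -> clock time, rounded to the nearest minute."""
    minutes = int(round(h * 60.0)) % 1440
    return Time(minutes // 60, minutes % 60)


# --------------------------------------------------------------------------
# raw observations

#: Physiologic sensor reporting range, mg/dL.
GLUCOSE_MIN, GLUCOSE_MAX = 20.0, 600.0


@dataclass
class GlucoseTrace:
    """One participant's ordered CGM series.

    ``readings`` has two columns: ``timestamp`` (naive local datetime64) and
    ``glucose`` (mg/dL). Timestamps must be strictly increasing and glucose
    must lie in the physiologic sensor range [20, 600] mg/dL.
    """

    participant_id: str
    readings: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.readings.columns)
        if cols[:2] != ["timestamp", "glucose"]:
            raise ValueError(
                f"trace readings need columns ['timestamp', 'glucose'], got {cols}"
            )
        ts = self.readings["timestamp"].to_numpy()
        if len(ts) > 1 and not (np.diff(ts.astype("datetime64[ns]").astype(np.int64)) > 0).all():
            raise ValueError(
                f"participant {self.participant_id!r}: timestamps not strictly increasing"
            )
        g = self.readings["glucose"].to_numpy(dtype=float)
        if len(g) and (not np.isfinite(g).all() or g.min() < GLUCOSE_MIN or g.max() > GLUCOSE_MAX):
            raise ValueError(
                f"participant {self.participant_id!r}: glucose outside "
                f"[{GLUCOSE_MIN}, {GLUCOSE_MAX}] mg/dL or non-finite"
            )

    def __len__(self) -> int:
        return len(self.readings)

    def sampling_interval_minutes(self) -> float:
        """Median spacing between consecutive readings, in minutes."""
        ts = self.readings["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64)
        if len(ts) < 2:
            return 5.0
        return float(np.median(np.diff(ts)) / 60.0)

    def day_slice(self, day: Date) -> pd.DataFrame:
        """Readings with timestamps in [day 00:00, next day 00:00)."""
        start = datetime.combine(day, Time(0, 0))
        stop = start + timedelta(days=1)
        ts = self.readings["timestamp"]
        return self.readings[(ts >= start) & (ts < stop)]


@dataclass
class MealDiaryDay:
    """One participant-day of self-reported eating times.

    ``overnight_times`` lists reported eating events; ``overnight_eating`` is
    true when any reported eating event (listed or a meal time) falls in the
    half-open window [00:00, 06:00).
    """

    participant_id: str
    date: Date
    breakfast_time: Time | None = None
    lunch_time: Time | None = None
    dinner_time: Time | None = None
    last_meal_time: Time | None = None
    overnight_times: list[Time] = field(default_factory=list)

    @property
    def overnight_eating(self) -> bool:
        events = list(self.overnight_times) + [
            t for t in (self.breakfast_time, self.lunch_time,
                        self.dinner_time, self.last_meal_time) if t is not None
        ]
        return any(time_to_hours(t) < 6.0 for t in events)


# --------------------------------------------------------------------------
# scored days and summaries

@dataclass
class DayMetrics:
    """Scored quantities for one participant-day.

    A day is *valid* when the diary reports breakfast and a last meal and no
    overnight eating, and the CGM covers the required windows. On invalid days
    ``delta_glucose`` and ``dp_day`` are absent; report-only fields (nadir,
    prebreakfast, 6 AM glucose) are filled whenever computable.
    """

    participant_id: str
    date: Date
    valid: bool
    invalid_reason: str | None = None
    nocturnal_nadir: float | None = None
    nadir_time: Time | None = None
    prebreakfast_glucose: float | None = None
    prebreakfast_source: str | None = None  # 'prebreakfast' | '10am_fallback'
    glucose_6am: float | None = None
    delta_glucose: float | None = None
    dp_day: bool | None = None

    def __post_init__(self) -> None:
        if not self.valid and (self.delta_glucose is not None or self.dp_day is not None):
            raise ValueError("invalid day must not carry delta_glucose or dp_day")
        if self.delta_glucose is not None and self.delta_glucose < 0:
            raise ValueError("delta_glucose must be >= 0 (0-floor rule)")


@dataclass
class ParticipantSummary:
    """Valid-day and dawn-phenomenon counts for one participant."""

    participant_id: str
    n_days_observed: int
    n_valid_days: int
    n_dp_days: int
    dp_percent: float | None          # 100 * n_dp_days / n_valid_days, absent if no valid days
    mean_delta_glucose: float | None  # over valid days
    excluded: bool                    # no valid days -> removed from DP analyses


def metrics_frame(days: Iterable[DayMetrics]) -> pd.DataFrame:
    """Tabulate DayMetrics records (one row per participant-day)."""
    rows = []
    for d in days:
        rows.append({
            "participant_id": d.participant_id,
            "date": d.date,
            "valid": d.valid,
            "invalid_reason": d.invalid_reason,
            "nocturnal_nadir": d.nocturnal_nadir,
            "nadir_time": d.nadir_time.strftime("%H:%M") if d.nadir_time else None,
            "prebreakfast_glucose": d.prebreakfast_glucose,
            "prebreakfast_source": d.prebreakfast_source,
            "glucose_6am": d.glucose_6am,
            "delta_glucose": d.delta_glucose,
            "dp_day": d.dp_day,
        })
    return pd.DataFrame(rows)


def summaries_frame(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": s.participant_id,
        "n_days_observed": s.n_days_observed,
        "n_valid_days": s.n_valid_days,
        "n_dp_days": s.n_dp_days,
        "dp_percent": s.dp_percent,
        "mean_delta_glucose": s.mean_delta_glucose,
        "excluded": s.excluded,
    } for s in summaries])


# --------------------------------------------------------------------------
# GGE thresholds and eating opportunities

@dataclass
class GgeThreshold:
    """Personalized glucose-guided-eating threshold.

    The threshold is the arithmetic mean of the prebreakfast glucose on two
    consecutive valid days; ``source_type`` records the DP status of the pair.
    """

    participant_id: str
    threshold: float
    source_dates: tuple[Date, Date]
    source_type: str  # 'DP-pair' | 'non-DP-pair' | 'mixed-pair'


@dataclass
class OpportunityCount:
    """Downward threshold crossings within one day's eating window."""

    participant_id: str
    date: Date
    threshold: float
    eating_window: tuple[Time, Time]
    n_opportunities: int | None  # absent when the window holds no readings


# --------------------------------------------------------------------------
# model fits

@dataclass
class CoefEstimate:
    """One fixed-effect estimate with Wald 95% CI and p-value."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class WithinBetweenFit:
    """Random-intercept model of prebreakfast glucose on DP status.

    ``between`` is the coefficient on the participant's valid-day DP
    proportion (mg/dL per unit proportion, i.e. the never-DP -> always-DP
    contrast); ``within`` is the coefficient on the day's deviation from that
    proportion (mg/dL per DP day).
    """

    intercept: CoefEstimate
    between: CoefEstimate
    within: CoefEstimate
    random_intercept_variance: float
    residual_variance: float
    n_participants: int
    n_days: int
    converged: bool


@dataclass
class AssociationResult:
    """Day-level Pearson correlation with Fisher-z 95% CI."""

    correlation: float
    ci_low: float
    ci_high: float
    r_squared: float
    p_value: float
    n_days: int


@dataclass
class SlopeFit:
    """Random-intercept regression of an outcome on last-meal clock hour."""

    outcome: str
    slope: CoefEstimate
    intercept: CoefEstimate
    n_pairs: int
    n_participants: int


@dataclass
class LastMealEffects:
    """Next-day effects of last-meal timing (prebreakfast glucose and ∂)."""

    prebreakfast: SlopeFit
    delta: SlopeFit


# --------------------------------------------------------------------------
# simulation ground truth

@dataclass
class GroundTruth:
    """Generator-side truth for every simulated participant-day.

    ``days`` columns: participant_id, date, dp_true, magnitude (the injected
    dawn rise, mg/dL, measured on the noise-free curve), nadir_true,
    prebreakfast_true, expected_valid. ``participants`` columns:
    participant_id, dp_probability, baseline_offset, n_days, dp_proportion.
    ``within_effect`` / ``between_effect`` are the coefficients the generator
    used (mg/dL).
    """

    days: pd.DataFrame
    participants: pd.DataFrame
    within_effect: float
    between_effect: float
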