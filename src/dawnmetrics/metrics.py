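"""Day-level dawn-phenomenon scoring.

For each participant-day with a well-formed diary the scorer computes:

* the nocturnal glucose nadir — the minimum reading in [00:00, 06:00), ties
  broken by earliest time;
* prebreakfast (morning preprandial) glucose — the last reading at or before
  breakfast within [06:00, 10:00], or the reading at 10:00 (nearest within
  half a sampling interval) when breakfast is later;
* ∂ glucose = max(prebreakfast − nadir, 0) — floored at zero when every
  nocturnal reading exceeds the prebreakfast level;
* the dawn-phenomenon flag: ∂ glucose ≥ 20 mg/dL (threshold configurable).

A day is valid when the diary reports breakfast and a last meal and no
eating between midnight and 6 AM. Days whose CGM lacks a required window
are demoted to invalid with a logged reason rather than interpolated.
"""

from __future__ import annotations

import logging
from datetime import date as Date, datetime, time as Time
from typing import Iterable, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import DawnMetricsError
from .types import (DayMetrics, GlucoseTrace, MealDiaryDay,
                    ParticipantSummary, hours_to_time, time_to_minutes)

logger = logging.getLogger(__name__)

__all__ = [
    "is_valid_day", "nocturnal_nadir", "prebreakfast_glucose", "delta_glucose",
    "classify_dp_day", "score_day", "score_cohort", "summarize_participant",
    "summarize_cohort",
]


def is_valid_day(diary: MealDiaryDay) -> bool:
    """True iff breakfast and last meal are reported and there is no eating
    event between midnight and 6 AM."""
    return (diary.breakfast_time is not None
            and diary.last_meal_time is not None
            and not diary.overnight_eating)


def _day_arrays(trace: GlucoseTrace, day: Date) -> tuple[np.ndarray, np.ndarray]:
    """(minutes-since-midnight, glucose) for one calendar date."""
    sl = trace.day_slice(day)
    if len(sl) == 0:
        return np.empty(0), np.empty(0)
    start = np.datetime64(datetime.combine(day, Time(0, 0)), "ns")
    minutes = (sl["timestamp"].to_numpy() - start) / np.timedelta64(60, "s")
    return minutes.astype(float), sl["glucose"].to_numpy(dtype=float)


def nocturnal_nadir(trace: GlucoseTrace, day: Date,
                    window: tuple[float, float] = (0.0, 6.0)) -> tuple[float, Time]:
    """Minimum glucose in the half-open nocturnal window and the clock time
    of its first attainment. Raises if the window holds no readings."""
    minutes, glucose = _day_arrays(trace, day)
    mask = (minutes >= window[0] * 60.0) & (minutes < window[1] * 60.0)
    if not mask.any():
        raise DawnMetricsError(
            f"participant {trace.participant_id!r} {day}: no readings in "
            f"nocturnal window [{window[0]:.0f}:00, {window[1]:.0f}:00)")
    g = glucose[mask]
    m = minutes[mask]
    idx = int(np.argmin(g))  # argmin returns the first minimum -> earliest time
    return float(g[idx]), hours_to_time(m[idx] / 60.0)


def prebreakfast_glucose(trace: GlucoseTrace, diary: MealDiaryDay,
                         window: tuple[float, float] = (6.0, 10.0),
                         ) -> tuple[float, str]:
    """Morning preprandial glucose and its source tag.

    When breakfast is at or before the window end (10:00), returns the last
    reading with timestamp <= breakfast time and >= window start. When
    breakfast is later, returns the reading nearest the window end within
    half a sampling interval (``'10am_fallback'``). Raises if no qualifying
    reading exists.
    """
    if diary.breakfast_time is None:
        raise DawnMetricsError(
            f"participant {diary.participant_id!r} {diary.date}: no breakfast reported")
    minutes, glucose = _day_arrays(trace, diary.date)
    bk_min = time_to_minutes(diary.breakfast_time)
    lo, hi = window[0] * 60.0, window[1] * 60.0
    if bk_min <= hi:
        mask = (minutes >= lo) & (minutes <= bk_min)
        if not mask.any():
            raise DawnMetricsError(
                f"participant {diary.participant_id!r} {diary.date}: no reading "
                f"between {window[0]:.0f}:00 and breakfast")
        idx = int(np.flatnonzero(mask)[-1])
        return float(glucose[idx]), "prebreakfast"
    half = trace.sampling_interval_minutes() / 2.0
    dist = np.abs(minutes - hi)
    idx = int(np.argmin(dist)) if len(dist) else -1
    if idx < 0 or dist[idx] > half:
        raise DawnMetricsError(
            f"participant {diary.participant_id!r} {diary.date}: no reading at "
            f"{window[1]:.0f}:00 for post-window breakfast")
    return float(glucose[idx]), "10am_fallback"


def delta_glucose(nadir: float, prebreakfast: float) -> float:
    """∂ glucose: prebreakfast minus nocturnal nadir, floored at 0."""
    return max(prebreakfast - nadir, 0.0)


def classify_dp_day(delta: float, threshold: float = 20.0) -> bool:
    """Dawn-phenomenon day: ∂ glucose greater than or equal to the threshold."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return delta >= threshold


def _glucose_at(trace: GlucoseTrace, day: Date, clock_hour: float) -> float | None:
    """Reading nearest ``clock_hour`` within half a sampling interval."""
    minutes, glucose = _day_arrays(trace, day)
    if len(minutes) == 0:
        return None
    dist = np.abs(minutes - clock_hour * 60.0)
    idx = int(np.argmin(dist))
    if dist[idx] > trace.sampling_interval_minutes() / 2.0:
        return None
    return float(glucose[idx])


def score_day(trace: GlucoseTrace, diary: MealDiaryDay,
              config: PipelineConfig | None = None) -> DayMetrics:
    """Score one participant-day; never raises for missing data, demoting the
    day to invalid with a reason instead."""
    config = config or PipelineConfig()
    reason = None
    if diary.breakfast_time is None:
        reason = "no_breakfast_reported"
    elif diary.last_meal_time is None:
        reason = "no_last_meal_reported"
    elif diary.overnight_eating:
        reason = "overnight_eating"

    nadir = nadir_time = None
    try:
        nadir, nadir_time = nocturnal_nadir(trace, diary.date, config.nocturnal_window)
    except DawnMetricsError:
        if reason is None:
            reason = "no_nocturnal_readings"
    preb = source = None
    if diary.breakfast_time is not None:
        try:
            preb, source = prebreakfast_glucose(trace, diary, config.breakfast_window)
        except DawnMetricsError:
            if reason is None:
                reason = "no_prebreakfast_reading"

    valid = reason is None
    if not valid and reason in ("no_nocturnal_readings", "no_prebreakfast_reading"):
        logger.info("demoting %s %s to invalid: %s",
                    diary.participant_id, diary.date, reason)

    delta = dp = None
    if valid:
        delta = delta_glucose(nadir, preb)
        dp = classify_dp_day(delta, config.dp_threshold)

    return DayMetrics(
        participant_id=diary.participant_id,
        date=diary.date,
        valid=valid,
        invalid_reason=reason,
        nocturnal_nadir=nadir,
        nadir_time=nadir_time,
        prebreakfast_glucose=preb,
        prebreakfast_source=source,
        glucose_6am=_glucose_at(trace, diary.date, config.nocturnal_window[1]),
        delta_glucose=delta,
        dp_day=dp,
    )


def score_cohort(traces: Sequence[GlucoseTrace], diaries: Sequence[MealDiaryDay],
                 config: PipelineConfig | None = None) -> list[DayMetrics]:
    """Score every diary day against its participant's trace.

    Diary days whose participant has no CGM trace are scored against an empty
    trace (and therefore demoted). Returns records sorted by participant and
    date; exactly one record per diary day.
    """
    config = config or PipelineConfig()
    config.validate()
    by_pid = {t.participant_id: t for t in traces}
    empty = {}
    out = []
    for diary in sorted(diaries, key=lambda d: (d.participant_id, d.date)):
        trace = by_pid.get(diary.participant_id)
        if trace is None:
            import pandas as pd
            trace = empty.setdefault(diary.participant_id, GlucoseTrace(
                diary.participant_id,
                pd.DataFrame({"timestamp": pd.DatetimeIndex([]), "glucose": []})))
        out.append(score_day(trace, diary, config))
    return out


def summarize_participant(days: Sequence[DayMetrics]) -> ParticipantSummary:
    """Collapse one participant's scored days to counts and DP percent."""
    if len(days) == 0:
        raise DawnMetricsError("cannot summarize an empty day list")
    pids = {d.participant_id for d in days}
    if len(pids) != 1:
        raise DawnMetricsError(f"days span multiple participants: {sorted(pids)}")
    valid = [d for d in days if d.valid]
    n_dp = sum(1 for d in valid if d.dp_day)
    n_valid = len(valid)
    return ParticipantSummary(
        participant_id=days[0].participant_id,
        n_days_observed=len(days),
        n_valid_days=n_valid,
        n_dp_days=n_dp,
        dp_percent=100.0 * n_dp / n_valid if n_valid else None,
        mean_delta_glucose=(float(np.mean([d.delta_glucose for d in valid]))
                            if n_valid else None),
        excluded=n_valid == 0,
    )


def summarize_cohort(days: Iterable[DayMetrics]) -> list[ParticipantSummary]:
    by_pid: dict[str, list[DayMetrics]] = {}
    for d in days:
        by_pid.setdefault(d.participant_id, []).append(d)
    return [summarize_participant(v) for _, v in sorted(by_pid.items())]
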