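"""Glucose-guided-eating (GGE) thresholds and eating opportunities.

A GGE threshold is the mean of the morning preprandial glucose on two
consecutive valid days; eating is permitted when hungry and when glucose is
at or below the threshold. Because the dawn phenomenon elevates morning
glucose, a threshold derived from two DP mornings sits higher — and permits
more eating opportunities — than one derived from two non-DP mornings.

An *eating opportunity* is a drop of the glucose trace to or below the
threshold inside the day's eating window [breakfast, last meal]: being at or
below the threshold at the first in-window reading counts once, and each
subsequent downward crossing (previous reading above, current at or below)
counts once more. Crossings are evaluated on raw readings; an optional
moving-average pre-filter is available but off by default.
"""

from __future__ import annotations

import logging
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoPairError
from .metrics import _day_arrays
from .types import (DayMetrics, GgeThreshold, GlucoseTrace, MealDiaryDay,
                    OpportunityCount, time_to_minutes)

logger = logging.getLogger(__name__)

__all__ = ["derive_threshold", "count_opportunities", "compare_thresholds",
           "consecutive_valid_pairs"]

PAIR_RULES = ("first-available", "any-pair", "both-DP", "both-non-DP")


def consecutive_valid_pairs(days: Sequence[DayMetrics]
                            ) -> list[tuple[DayMetrics, DayMetrics]]:
    """Calendar-adjacent pairs of valid days (a gap or an intervening invalid
    day disqualifies the pair), in chronological order."""
    valid = sorted((d for d in days if d.valid), key=lambda d: d.date)
    return [(a, b) for a, b in zip(valid, valid[1:])
            if b.date - a.date == timedelta(days=1)]


def _pair_type(a: DayMetrics, b: DayMetrics) -> str:
    if a.dp_day and b.dp_day:
        return "DP-pair"
    if not a.dp_day and not b.dp_day:
        return "non-DP-pair"
    return "mixed-pair"


def derive_threshold(days: Sequence[DayMetrics],
                     selection: str = "first-available") -> GgeThreshold:
    """Personalized GGE threshold from the first qualifying pair of
    consecutive valid mornings.

    ``selection`` restricts the pair: ``'both-DP'`` / ``'both-non-DP'``
    require matching DP status; ``'first-available'`` (alias ``'any-pair'``)
    takes the earliest pair regardless. Raises :class:`NoPairError` when no
    pair qualifies.
    """
    if selection not in PAIR_RULES:
        raise ValueError(f"unknown pair rule {selection!r}")
    pids = {d.participant_id for d in days}
    if len(pids) != 1:
        raise ValueError(f"days must belong to one participant, got {sorted(pids)}")
    pid = next(iter(pids))
    for a, b in consecutive_valid_pairs(days):
        ptype = _pair_type(a, b)
        if selection == "both-DP" and ptype != "DP-pair":
            continue
        if selection == "both-non-DP" and ptype != "non-DP-pair":
            continue
        return GgeThreshold(
            participant_id=pid,
            threshold=(a.prebreakfast_glucose + b.prebreakfast_glucose) / 2.0,
            source_dates=(a.date, b.date),
            source_type=ptype,
        )
    raise NoPairError(pid, selection)


def _moving_average(g: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return g
    kernel = np.ones(width) / width
    # same-length smoothing with edge padding
    padded = np.concatenate([np.full(width // 2, g[0]), g,
                             np.full(width - 1 - width // 2, g[-1])])
    return np.convolve(padded, kernel, mode="valid")


def count_opportunities(trace: GlucoseTrace, diary: MealDiaryDay,
                        threshold: float, smoothing_width: int = 0
                        ) -> OpportunityCount:
    """Count eating opportunities for one day under a GGE threshold.

    Uses readings inside the inclusive eating window [breakfast, last meal].
    If the window holds no readings the count is absent with a warning.
    """
    if diary.breakfast_time is None or diary.last_meal_time is None:
        raise ValueError("eating window requires breakfast and last-meal times")
    window = (diary.breakfast_time, diary.last_meal_time)
    minutes, glucose = _day_arrays(trace, diary.date)
    lo = time_to_minutes(diary.breakfast_time)
    hi = time_to_minutes(diary.last_meal_time)
    mask = (minutes >= lo) & (minutes <= hi)
    if not mask.any():
        logger.warning("participant %s %s: no readings in eating window",
                       diary.participant_id, diary.date)
        return OpportunityCount(diary.participant_id, diary.date, threshold,
                                window, None)
    g = _moving_average(glucose[mask], smoothing_width)
    below = g <= threshold
    n = int(below[0]) + int(np.sum(~below[:-1] & below[1:]))
    return OpportunityCount(diary.participant_id, diary.date, threshold,
                            window, n)


def compare_thresholds(days: Sequence[DayMetrics], trace: GlucoseTrace,
                       diaries: Sequence[MealDiaryDay],
                       smoothing_width: int = 0) -> pd.DataFrame:
    """Per-day opportunity counts under the DP-pair vs non-DP-pair thresholds.

    Derives both thresholds for the participant (raising
    :class:`NoPairError` when either pair type is unavailable) and counts
    opportunities on every valid day with an eating window. Returns one row
    per day with both counts and their paired difference.
    """
    thr_dp = derive_threshold(days, "both-DP")
    thr_non = derive_threshold(days, "both-non-DP")
    diary_by_date = {d.date: d for d in diaries
                     if d.participant_id == trace.participant_id}
    rows = []
    for day in days:
        if not day.valid or day.date not in diary_by_date:
            continue
        diary = diary_by_date[day.date]
        c_dp = count_opportunities(trace, diary, thr_dp.threshold, smoothing_width)
        c_non = count_opportunities(trace, diary, thr_non.threshold, smoothing_width)
        if c_dp.n_opportunities is None or c_non.n_opportunities is None:
            continue
        rows.append({
            "participant_id": day.participant_id,
            "date": day.date,
            "dp_day": day.dp_day,
            "threshold_dp_pair": thr_dp.threshold,
            "threshold_nondp_pair": thr_non.threshold,
            "n_opportunities_dp_pair": c_dp.n_opportunities,
            "n_opportunities_nondp_pair": c_non.n_opportunities,
            "difference": c_dp.n_opportunities - c_non.n_opportunities,
        })
    return pd.DataFrame(rows)
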