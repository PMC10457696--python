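"""Day-level scoring rules: validity, windows, ∂ glucose, DP classification."""

from datetime import date as Date, time as Time

import numpy as np
import pytest

from dawnmetrics import (PipelineConfig, classify_dp_day, delta_glucose,
                         is_valid_day, metrics_frame, nocturnal_nadir,
                         prebreakfast_glucose, score_cohort, score_day,
                         summarize_participant)
from dawnmetrics.errors import DawnMetricsError
from dawnmetrics.types import DayMetrics

from conftest import DAY, make_diary, make_trace


class TestValidDay:
    def test_breakfast_and_last_meal_no_overnight_is_valid(self):
        assert is_valid_day(make_diary("A", DAY, breakfast=8.0, last=20.5))

    def test_missing_last_meal_invalidates(self):
        assert not is_valid_day(make_diary("A", DAY, breakfast=8.0))

    def test_missing_breakfast_invalidates(self):
        assert not is_valid_day(make_diary("A", DAY, last=20.5))

    def test_overnight_eating_invalidates(self):
        d = make_diary("A", DAY, breakfast=8.0, last=20.5, overnight=[3.0])
        assert not is_valid_day(d)

    def test_eating_at_six_sharp_does_not_invalidate(self):
        d = make_diary("A", DAY, breakfast=8.0, last=20.5, overnight=[6.0])
        assert is_valid_day(d)


class TestPrebreakfast:
    def test_last_reading_at_or_before_breakfast(self):
        trace = make_trace("A", DAY, np.arange(360, 600, 5),
                           np.arange(100, 148, 1))
        diary = make_diary("A", DAY, breakfast=Time(8, 17), last=20.5)
        value, source = prebreakfast_glucose(trace, diary)
        # 08:15 is the last 5-minute reading at or before 08:17
        assert source == "prebreakfast"
        assert value == trace.readings.set_index("timestamp")["glucose"].loc[
            f"{DAY}T08:15"]

    def test_late_breakfast_uses_ten_am_reading(self):
        trace = make_trace("A", DAY, np.arange(0, 1440, 5),
                           np.full(288, 120.0))
        trace.readings.loc[trace.readings["timestamp"] == f"{DAY}T10:00",
                           "glucose"] = 133.0
        diary = make_diary("A", DAY, breakfast=Time(10, 30), last=20.5)
        value, source = prebreakfast_glucose(trace, diary)
        assert (value, source) == (133.0, "10am_fallback")

    def test_breakfast_at_six_sharp_uses_six_am_reading(self):
        trace = make_trace("A", DAY, [355, 360, 365], [100.0, 111.0, 122.0])
        diary = make_diary("A", DAY, breakfast=Time(6, 0), last=20.5)
        assert prebreakfast_glucose(trace, diary) == (111.0, "prebreakfast")

    def test_no_qualifying_reading_raises(self):
        trace = make_trace("A", DAY, [100, 200], [100.0, 100.0])  # night only
        diary = make_diary("A", DAY, breakfast=8.0, last=20.5)
        with pytest.raises(DawnMetricsError):
            prebreakfast_glucose(trace, diary)


class TestNocturnalNadir:
    def test_minimum_and_time(self):
        trace = make_trace("A", DAY, [60, 180, 300], [110.0, 95.0, 101.0])
        assert nocturnal_nadir(trace, DAY) == (95.0, Time(3, 0))

    def test_tie_broken_by_earliest_time(self):
        trace = make_trace("A", DAY, [120, 180, 240], [95.0, 100.0, 95.0])
        assert nocturnal_nadir(trace, DAY) == (95.0, Time(2, 0))

    def test_single_reading(self):
        trace = make_trace("A", DAY, [5], [120.0])
        assert nocturnal_nadir(trace, DAY) == (120.0, Time(0, 5))

    def test_window_is_half_open_at_six(self):
        # the 06:00 reading (value 50) is outside [00:00, 06:00)
        trace = make_trace("A", DAY, [100, 360], [90.0, 50.0])
        assert nocturnal_nadir(trace, DAY)[0] == 90.0

    def test_empty_window_raises(self):
        trace = make_trace("A", DAY, [400, 500], [100.0, 100.0])
        with pytest.raises(DawnMetricsError, match="nocturnal window"):
            nocturnal_nadir(trace, DAY)


@pytest.mark.parametrize("nadir, preb, expected", [
    (100.0, 125.0, 25.0),
    (130.0, 120.0, 0.0),   # nocturnal glucose above prebreakfast -> floored
    (100.0, 100.0, 0.0),
])
def test_delta_glucose_floors_at_zero(nadir, preb, expected):
    assert delta_glucose(nadir, preb) == expected


@pytest.mark.parametrize("delta, expected", [
    (20.0, True),    # threshold inclusive
    (19.9, False),
    (0.0, False),
    (45.0, True),
])
def test_classify_dp_day_threshold_inclusive(delta, expected):
    assert classify_dp_day(delta) is expected


def test_missing_cgm_window_demotes_day():
    """A diary-valid day without nocturnal CGM coverage is demoted, and the
    demotion reason is recorded."""
    trace = make_trace("A", DAY, np.arange(360, 1440, 5),
                       np.full(216, 120.0))  # nothing before 06:00
    diary = make_diary("A", DAY, breakfast=8.0, last=20.5)
    m = score_day(trace, diary)
    assert not m.valid
    assert m.invalid_reason == "no_nocturnal_readings"
    assert m.delta_glucose is None and m.dp_day is None


class TestSummarize:
    @staticmethod
    def _mk_days(pid, n_valid, n_dp, n_invalid=0):
        days = []
        for i in range(n_valid):
            dp = i < n_dp
            days.append(DayMetrics(pid, Date(2021, 6, 1 + i), True,
                                   nocturnal_nadir=100.0,
                                   prebreakfast_glucose=125.0,
                                   delta_glucose=25.0 if dp else 5.0,
                                   dp_day=dp))
        for i in range(n_invalid):
            days.append(DayMetrics(pid, Date(2021, 6, 20 + i), False,
                                   invalid_reason="overnight_eating"))
        return days

    def test_percent_of_valid_days(self):
        s = summarize_participant(self._mk_days("A", 8, 4))
        assert (s.n_valid_days, s.n_dp_days, s.dp_percent) == (8, 4, 50.0)

    def test_all_dp_among_valid(self):
        s = summarize_participant(self._mk_days("A", 5, 5, n_invalid=5))
        assert s.n_days_observed == 10
        assert (s.n_valid_days, s.dp_percent) == (5, 100.0)

    def test_zero_valid_days_excluded(self):
        s = summarize_participant(self._mk_days("A", 0, 0, n_invalid=4))
        assert s.excluded and s.dp_percent is None and s.mean_delta_glucose is None

    def test_empty_input_raises(self):
        with pytest.raises(DawnMetricsError):
            summarize_participant([])

    def test_mixed_participants_raise(self):
        days = self._mk_days("A", 2, 1) + self._mk_days("B", 2, 1)
        with pytest.raises(DawnMetricsError):
            summarize_participant(days)


def test_nadir_matches_exhaustive_scan(noise_free_cohort):
    """Scored nadir equals a brute-force scan over the raw window readings."""
    traces, diaries, _ = noise_free_cohort
    days = score_cohort(traces, diaries)
    by_pid = {t.participant_id: t for t in traces}
    checked = 0
    for m in days:
        if not m.valid:
            continue
        sl = by_pid[m.participant_id].day_slice(m.date)
        window = [(ts, g) for ts, g in zip(sl["timestamp"], sl["glucose"])
                  if ts.hour < 6]
        best = min(window, key=lambda p: (p[1], p[0]))
        assert m.nocturnal_nadir == best[1]
        assert m.nadir_time == best[0].time()
        checked += 1
    assert checked > 100


def test_raising_threshold_never_raises_dp_percent(default_cohort):
    """DP percent is monotone non-increasing in the DP threshold."""
    traces, diaries, _ = default_cohort
    prev = None
    for thr in (10.0, 20.0, 30.0, 40.0):
        days = score_cohort(traces, diaries, PipelineConfig(dp_threshold=thr))
        df = metrics_frame(days)
        pct = (df[df["valid"]].groupby("participant_id")["dp_day"]
               .mean().sort_index() * 100)
        if prev is not None:
            assert (pct <= prev + 1e-12).all()
        prev = pct


def test_day_accounting_conserved(default_cohort):
    """observed = valid + invalid, and one scored record per diary day."""
    traces, diaries, _ = default_cohort
    days = score_cohort(traces, diaries)
    assert len(days) == len(diaries)
    df = metrics_frame(days)
    assert df["valid"].sum() + (~df["valid"]).sum() == len(diaries)
    per_pid = df.groupby("participant_id").size()
    from collections import Counter
    diary_counts = Counter(d.participant_id for d in diaries)
    assert dict(per_pid) == dict(diary_counts)
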