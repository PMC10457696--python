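"""Mixed-model and association estimators."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from dawnmetrics import (DegenerateDesignError, SimulationConfig,
                         UndefinedCorrelationError, fit_association,
                         fit_last_meal_effects, fit_within_between,
                         mealtime_summary, score_cohort, simulate_cohort)
from dawnmetrics.types import DayMetrics

from conftest import DAY, make_diary, make_trace


def _day(pid, date, preb, dp, delta=None):
    return DayMetrics(pid, date, True, nocturnal_nadir=100.0,
                      prebreakfast_glucose=preb,
                      delta_glucose=(preb - 100.0 if delta is None else delta),
                      dp_day=dp)


def _synthetic_days(rng, n_pid=30, n_days=10, gw=12.0, gb=54.0, sd_u=15.0,
                    sd_e=12.0):
    """Days drawn exactly from the within/between model."""
    days = []
    for i in range(n_pid):
        p = rng.uniform(0.1, 0.9)
        x = rng.random(n_days) < p
        xbar = x.mean()
        u = rng.normal(0, sd_u)
        for j in range(n_days):
            y = 105.0 + gb * xbar + gw * (x[j] - xbar) + u + rng.normal(0, sd_e)
            days.append(_day(f"P{i:03d}", DAY + timedelta(days=j), y, bool(x[j]),
                             delta=30.0 if x[j] else 5.0))
    return days


class TestWithinBetween:
    def test_recovers_injected_effects(self):
        rng = np.random.default_rng(42)
        fit = fit_within_between(_synthetic_days(rng, n_pid=200, n_days=10))
        assert abs(fit.within.estimate - 12.0) < 2.0
        assert abs(fit.between.estimate - 54.0) < 10.0
        assert fit.within.ci_low <= fit.within.estimate <= fit.within.ci_high

    def test_all_dp_indicators_zero_is_degenerate(self):
        days = [_day("A", DAY + timedelta(days=j), 120.0 + j, False)
                for j in range(5)]
        days += [_day("B", DAY + timedelta(days=j), 110.0 + j, False)
                 for j in range(5)]
        with pytest.raises(DegenerateDesignError, match="within"):
            fit_within_between(days)

    def test_single_participant_is_degenerate(self):
        days = [_day("A", DAY + timedelta(days=j), 120.0, j % 2 == 0)
                for j in range(6)]
        with pytest.raises(DegenerateDesignError):
            fit_within_between(days)

    def test_within_estimate_equals_centered_ols_when_balanced(self):
        """With a balanced design the within coefficient of the mixed model
        equals the pooled OLS slope on the person-centered DP indicator."""
        rng = np.random.default_rng(7)
        days = _synthetic_days(rng, n_pid=40, n_days=8)
        fit = fit_within_between(days)
        df = pd.DataFrame({
            "pid": [d.participant_id for d in days],
            "y": [d.prebreakfast_glucose for d in days],
            "x": [float(d.dp_day) for d in days]})
        df["xdev"] = df["x"] - df.groupby("pid")["x"].transform("mean")
        df["ydev"] = df["y"] - df.groupby("pid")["y"].transform("mean")
        slope = (df["xdev"] * df["ydev"]).sum() / (df["xdev"] ** 2).sum()
        assert abs(fit.within.estimate - slope) < 0.05

    def test_variance_components_nonnegative(self, default_cohort):
        traces, diaries, _ = default_cohort
        fit = fit_within_between(score_cohort(traces, diaries))
        assert fit.random_intercept_variance >= 0
        assert fit.residual_variance > 0
        assert fit.n_participants >= 20


class TestAssociation:
    def test_perfect_linear_relation(self):
        days = [_day("A", DAY + timedelta(days=j), 100.0 + 2 * j, False,
                     delta=float(j)) for j in range(10)]
        res = fit_association(days)
        assert res.correlation == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        days = [_day("A", DAY + timedelta(days=int(j)), rng.normal(130, 20),
                     False, delta=float(abs(rng.normal(10, 5))))
                for j in range(10000)]
        res = fit_association(days)
        assert abs(res.correlation) < 0.05  # ~4 Fisher-z SEs at n=10000

    def test_ci_asymmetric_about_r(self, default_cohort):
        traces, diaries, _ = default_cohort
        res = fit_association(score_cohort(traces, diaries))
        assert res.ci_low < res.correlation < res.ci_high
        # Fisher-z back-transform compresses the side nearer |r| = 1
        assert (res.correlation - res.ci_low) != pytest.approx(
            res.ci_high - res.correlation, rel=1e-3)
        assert res.r_squared == pytest.approx(res.correlation ** 2)

    def test_zero_variance_raises(self):
        days = [_day("A", DAY + timedelta(days=j), 120.0, False, delta=5.0)
                for j in range(5)]
        with pytest.raises(UndefinedCorrelationError):
            fit_association(days)


class TestLastMealEffects:
    def test_single_participant_raises(self):
        days = [_day("A", DAY + timedelta(days=j), 120.0, j % 2 == 0)
                for j in range(6)]
        diaries = [make_diary("A", DAY + timedelta(days=j), breakfast=8.0,
                              last=20.5) for j in range(6)]
        with pytest.raises(DegenerateDesignError, match="participants"):
            fit_last_meal_effects(days, diaries)

    def test_null_generator_gives_null_slope(self, default_cohort):
        """The generator ties the dawn rise to nothing but DP status, so the
        last-meal slope on next-day ∂ should be small and non-significant at
        cohort scale."""
        traces, diaries, _ = default_cohort
        days = score_cohort(traces, diaries)
        fits = fit_last_meal_effects(days, diaries)
        assert fits.delta.n_participants >= 15
        assert fits.delta.slope.ci_low < 0 < fits.delta.slope.ci_high

    def test_injected_dependence_recovered(self):
        """A +2 mg/dL-per-hour dependence of next-day prebreakfast glucose on
        last-meal hour, injected post hoc, is recovered within tolerance."""
        cfg = SimulationConfig(n_participants=80, rng_seed=17,
                               overnight_every_day_participants=0,
                               breakfast_missing_probability=0.0,
                               last_meal_missing_probability=0.0,
                               overnight_eating_probability=0.0)
        traces, diaries, _ = simulate_cohort(cfg)
        days = score_cohort(traces, diaries)
        last_by_key = {(d.participant_id, d.date): d.last_meal_time
                       for d in diaries}
        bumped = []
        for d in days:
            prev = last_by_key.get((d.participant_id, d.date - timedelta(days=1)))
            if d.valid and prev is not None:
                h = prev.hour + prev.minute / 60.0
                bumped.append(DayMetrics(
                    d.participant_id, d.date, True,
                    nocturnal_nadir=d.nocturnal_nadir,
                    prebreakfast_glucose=d.prebreakfast_glucose + 2.0 * h,
                    delta_glucose=d.delta_glucose, dp_day=d.dp_day))
            else:
                bumped.append(d)
        fits = fit_last_meal_effects(bumped, diaries)
        assert fits.prebreakfast.slope.estimate == pytest.approx(2.0, abs=0.75)


class TestMealtimeSummary:
    def test_two_point_mean_and_sd(self):
        days = [_day("A", DAY, 120.0, True, delta=25.0),
                _day("A", DAY + timedelta(days=1), 130.0, True, delta=30.0)]
        diaries = [make_diary("A", DAY, breakfast=8.0, last=20.5),
                   make_diary("A", DAY + timedelta(days=1), breakfast=8.0,
                              last=20.5)]
        minutes = np.arange(0, 1440, 5.0)
        trace = make_trace("A", DAY, minutes, np.full(len(minutes), 120.0))
        out = mealtime_summary(days, diaries, [trace])
        dp = out[(out["stratum"] == "dp_days")
                 & (out["variable"] == "prebreakfast_glucose")].iloc[0]
        assert dp["mean"] == pytest.approx(125.0)
        assert dp["sd"] == pytest.approx(7.0711, abs=1e-3)

    def test_empty_stratum_absent(self):
        days = [_day("A", DAY, 120.0, False, delta=5.0),
                _day("A", DAY + timedelta(days=1), 121.0, False, delta=6.0)]
        diaries = [make_diary("A", DAY, breakfast=8.0, last=20.5),
                   make_diary("A", DAY + timedelta(days=1), breakfast=8.0,
                              last=20.5)]
        trace = make_trace("A", DAY, np.arange(0, 1440, 5.0),
                           np.full(288, 120.0))
        out = mealtime_summary(days, diaries, [trace])
        assert "dp_days" not in set(out["stratum"])

    def test_strata_counts_partition_valid_days(self, default_cohort):
        traces, diaries, _ = default_cohort
        days = score_cohort(traces, diaries)
        out = mealtime_summary(days, diaries, traces)
        n = {s: int(out[(out["stratum"] == s) & (out["variable"] == "n_days")]
                    ["n"].iloc[0]) for s in ("all_days", "dp_days", "non_dp_days")}
        n_valid = sum(1 for d in days if d.valid)
        assert n["dp_days"] + n["non_dp_days"] == n_valid
        assert n["all_days"] == len(diaries)
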