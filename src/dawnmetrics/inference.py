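"""Statistical models for dawn-phenomenon effects.

The central model decomposes the effect of the dawn phenomenon (DP) on
morning preprandial glucose into between- and within-person parts:

    y_ij = g0 + gB * xbar_i + gW * (x_ij - xbar_i) + u_i + e_ij

with y_ij the prebreakfast glucose on day j of participant i, x_ij the DP
indicator (0/1), xbar_i the participant's DP proportion over valid days
(entered on the [0, 1] scale, so gB is the never-DP -> always-DP contrast),
u_i a participant random intercept, and e_ij residual noise. Estimation is
restricted maximum likelihood with Wald 95% intervals.

Also provided: the day-level Pearson association between ∂ glucose and
prebreakfast glucose (Fisher-z interval, clustering ignored by design, with
a cluster-robust regression slope available as an option), mixed models for
next-day effects of last-meal timing, and the mealtime glucose summary
stratified by DP status.
"""

from __future__ import annotations

import warnings
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (ConvergenceError, DegenerateDesignError,
                     UndefinedCorrelationError)
from .metrics import _day_arrays
from .types import (AssociationResult, CoefEstimate, DayMetrics, GlucoseTrace,
                    LastMealEffects, MealDiaryDay, SlopeFit, WithinBetweenFit,
                    time_to_hours, time_to_minutes)

__all__ = ["fit_within_between", "fit_association", "fit_last_meal_effects",
           "mealtime_summary"]

_Z95 = stats.norm.ppf(0.975)


def _valid_frame(days: Sequence[DayMetrics]) -> pd.DataFrame:
    rows = [{"participant_id": d.participant_id, "date": d.date,
             "prebreakfast": d.prebreakfast_glucose, "delta": d.delta_glucose,
             "dp": float(d.dp_day)}
            for d in days if d.valid]
    return pd.DataFrame(rows)


def _coef(est: float, se: float) -> CoefEstimate:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2.0 * stats.norm.sf(abs(z))
    return CoefEstimate(estimate=float(est), se=float(se),
                        ci_low=float(est - _Z95 * se),
                        ci_high=float(est + _Z95 * se), p_value=float(p))


def _fit_mixedlm(y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """REML fit with a small ladder of optimizers; the random-intercept
    variance often sits on the zero boundary in small cohorts, where the
    default optimizer can report non-convergence."""
    model = sm.MixedLM(y, exog, groups=groups)
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "lbfgs", "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kwargs)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
                continue
            if res.converged:
                return res
            last = res
    if isinstance(last, Exception):
        raise ConvergenceError(f"mixed model failed: {last}") from last
    raise ConvergenceError(
        "mixed model did not converge under any optimizer; "
        f"fe_params={np.asarray(last.fe_params).round(4).tolist()}")


def fit_within_between(days: Sequence[DayMetrics]) -> WithinBetweenFit:
    """Fit the within/between-person DP model of prebreakfast glucose.

    Requires at least two participants with two or more valid days each.
    Raises :class:`DegenerateDesignError` when either the within-person
    deviation or the between-person proportion is constant (e.g. no DP days
    at all), and :class:`ConvergenceError` on a failed fit.
    """
    df = _valid_frame(days)
    if df.empty:
        raise DegenerateDesignError("no valid days to fit")
    sizes = df.groupby("participant_id").size()
    if (sizes >= 2).sum() < 2:
        raise DegenerateDesignError(
            "need >= 2 participants with >= 2 valid days each")
    df["xbar"] = df.groupby("participant_id")["dp"].transform("mean")
    df["xdev"] = df["dp"] - df["xbar"]
    if float(np.var(df["xdev"])) < 1e-12:
        raise DegenerateDesignError(
            "within-person DP deviation is constant (no within-person contrast)")
    if float(np.var(df["xbar"])) < 1e-12:
        raise DegenerateDesignError(
            "between-person DP proportion is constant across participants")

    exog = np.column_stack([np.ones(len(df)), df["xbar"], df["xdev"]])
    res = _fit_mixedlm(df["prebreakfast"].to_numpy(), exog,
                       df["participant_id"].to_numpy())
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    return WithinBetweenFit(
        intercept=_coef(fe[0], se[0]),
        between=_coef(fe[1], se[1]),
        within=_coef(fe[2], se[2]),
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]),
        residual_variance=float(res.scale),
        n_participants=int(df["participant_id"].nunique()),
        n_days=int(len(df)),
        converged=bool(res.converged),
    )


def fit_association(days: Sequence[DayMetrics],
                    cluster_robust_slope: bool = False) -> AssociationResult:
    """Day-level Pearson correlation between ∂ glucose and prebreakfast
    glucose with a Fisher-z 95% CI.

    Clustering within participants is ignored so the estimate mirrors a
    simple day-level scatter; set ``cluster_robust_slope`` to also check a
    day-level regression slope with cluster-robust (participant) errors —
    the result then carries that slope's p-value instead of the
    correlation's.
    """
    df = _valid_frame(days)
    if len(df) < 3:
        raise UndefinedCorrelationError("need >= 3 valid days")
    x = df["delta"].to_numpy(dtype=float)
    y = df["prebreakfast"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a variable has zero variance")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    p_value = float(res.pvalue)
    if cluster_robust_slope:
        ols = sm.OLS(y, sm.add_constant(x)).fit(
            cov_type="cluster", cov_kwds={"groups": df["participant_id"]})
        p_value = float(ols.pvalues[1])
    r = float(res.statistic)
    return AssociationResult(correlation=r, ci_low=float(ci.low),
                             ci_high=float(ci.high), r_squared=r * r,
                             p_value=p_value, n_days=len(df))


def _slope_fit(df: pd.DataFrame, outcome: str) -> SlopeFit:
    exog = np.column_stack([np.ones(len(df)), df["last_meal_hour"]])
    res = _fit_mixedlm(df[outcome].to_numpy(), exog,
                       df["participant_id"].to_numpy())
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    return SlopeFit(outcome=outcome, slope=_coef(fe[1], se[1]),
                    intercept=_coef(fe[0], se[0]), n_pairs=int(len(df)),
                    n_participants=int(df["participant_id"].nunique()))


def fit_last_meal_effects(days: Sequence[DayMetrics],
                          diaries: Sequence[MealDiaryDay]) -> LastMealEffects:
    """Effect of last-meal clock hour on the *next* day's prebreakfast
    glucose and ∂ glucose, each as a random-intercept mixed model.

    Pairs a diary day's last-meal time with the following calendar day's
    valid metrics. Requires pairs from at least two participants.
    """
    metrics_by_key = {(d.participant_id, d.date): d for d in days if d.valid}
    rows = []
    for diary in diaries:
        if diary.last_meal_time is None:
            continue
        nxt = metrics_by_key.get((diary.participant_id,
                                  diary.date + timedelta(days=1)))
        if nxt is None:
            continue
        rows.append({"participant_id": diary.participant_id,
                     "last_meal_hour": time_to_hours(diary.last_meal_time),
                     "prebreakfast": nxt.prebreakfast_glucose,
                     "delta": nxt.delta_glucose})
    df = pd.DataFrame(rows)
    if df.empty or df["participant_id"].nunique() < 2:
        raise DegenerateDesignError(
            "next-day pairing requires >= 2 participants (random intercept "
            "unidentifiable otherwise)")
    if float(np.var(df["last_meal_hour"])) < 1e-12:
        raise DegenerateDesignError("last-meal time is constant")
    return LastMealEffects(prebreakfast=_slope_fit(df, "prebreakfast"),
                           delta=_slope_fit(df, "delta"))


def _premeal_glucose(trace: GlucoseTrace, diary: MealDiaryDay,
                     meal_time) -> float | None:
    """Last reading at or before the logged mealtime (same day)."""
    if meal_time is None:
        return None
    minutes, glucose = _day_arrays(trace, diary.date)
    mask = minutes <= time_to_minutes(meal_time)
    if not mask.any():
        return None
    return float(glucose[np.flatnonzero(mask)[-1]])


def mealtime_summary(days: Sequence[DayMetrics], diaries: Sequence[MealDiaryDay],
                     traces: Sequence[GlucoseTrace]) -> pd.DataFrame:
    """Mean (SD) glucose at reported mealtimes, stratified by DP status.

    Strata: ``all_days`` (every observed day), ``dp_days`` and
    ``non_dp_days`` (valid days only). Variables: 6 AM glucose, breakfast and
    last-meal clock hours, and pre-breakfast/lunch/dinner glucose (last
    reading at or before the logged time). Empty strata are omitted rather
    than reported as zeros. Returns a tidy frame with columns
    ``stratum, variable, n, mean, sd``.
    """
    by_pid = {t.participant_id: t for t in traces}
    metrics_by_key = {(d.participant_id, d.date): d for d in days}
    records = []
    for diary in diaries:
        trace = by_pid.get(diary.participant_id)
        if trace is None:
            continue
        m = metrics_by_key.get((diary.participant_id, diary.date))
        records.append({
            "valid": m.valid if m else False,
            "dp": m.dp_day if (m and m.valid) else None,
            "glucose_6am": m.glucose_6am if m else None,
            "prebreakfast_glucose": m.prebreakfast_glucose if m else None,
            "breakfast_hour": (time_to_hours(diary.breakfast_time)
                               if diary.breakfast_time else None),
            "last_meal_hour": (time_to_hours(diary.last_meal_time)
                               if diary.last_meal_time else None),
            "prelunch_glucose": _premeal_glucose(trace, diary, diary.lunch_time),
            "predinner_glucose": _premeal_glucose(trace, diary, diary.dinner_time),
        })
    df = pd.DataFrame(records)
    variables = ["glucose_6am", "breakfast_hour", "prebreakfast_glucose",
                 "prelunch_glucose", "predinner_glucose", "last_meal_hour"]
    strata = {
        "all_days": df,
        "non_dp_days": df[df["dp"] == False],  # noqa: E712 (None-safe filter)
        "dp_days": df[df["dp"] == True],  # noqa: E712
    }
    rows = []
    for name, sub in strata.items():
        if sub.empty:
            continue
        rows.append({"stratum": name, "variable": "n_days", "n": len(sub),
                     "mean": float(len(sub)), "sd": 0.0})
        for var in variables:
            vals = sub[var].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            rows.append({"stratum": name, "variable": var, "n": len(vals),
                         "mean": float(np.mean(vals)),
                         "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)
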