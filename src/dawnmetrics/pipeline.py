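"""End-to-end orchestration: ingest -> score -> GGE -> models -> report.

``run_pipeline`` is deterministic given its inputs and configuration: every
output file (day metrics, participant summaries, thresholds, opportunity
counts, model fits, cohort report) is written with fixed float formatting so
a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .config import PipelineConfig
from .errors import (DawnMetricsError, DegenerateDesignError, NoPairError,
                     PipelineStageError)
from .gge import compare_thresholds, derive_threshold
from .inference import (fit_association, fit_last_meal_effects,
                        fit_within_between, mealtime_summary)
from .metrics import score_cohort, summarize_cohort
from .types import (DayMetrics, GlucoseTrace, MealDiaryDay,
                    ParticipantSummary, summaries_frame)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "analyze_cohort", "PipelineResult", "build_report"]


@dataclasses.dataclass
class PipelineResult:
    """Everything the pipeline computes, plus the report dictionary."""

    day_metrics: list[DayMetrics]
    summaries: list[ParticipantSummary]
    thresholds: pd.DataFrame
    opportunities: pd.DataFrame
    within_between: "WithinBetweenFit | None"
    association: "AssociationResult | None"
    last_meal: "LastMealEffects | None"
    mealtime: pd.DataFrame
    report: dict


def _threshold_table(days_by_pid: dict[str, list[DayMetrics]]) -> pd.DataFrame:
    rows = []
    for pid, days in sorted(days_by_pid.items()):
        for rule in ("first-available", "both-DP", "both-non-DP"):
            try:
                thr = derive_threshold(days, rule)
                rows.append({"participant_id": pid, "pair_rule": rule,
                             "threshold": thr.threshold,
                             "source_type": thr.source_type,
                             "source_date_1": thr.source_dates[0].isoformat(),
                             "source_date_2": thr.source_dates[1].isoformat()})
            except NoPairError:
                logger.info("participant %s: no %s pair", pid, rule)
    return pd.DataFrame(rows)


def _opportunity_table(days_by_pid, traces, diaries, smoothing) -> pd.DataFrame:
    by_pid_trace = {t.participant_id: t for t in traces}
    frames = []
    for pid, days in sorted(days_by_pid.items()):
        trace = by_pid_trace.get(pid)
        if trace is None:
            continue
        try:
            frames.append(compare_thresholds(days, trace, diaries, smoothing))
        except NoPairError:
            logger.info("participant %s: skipped opportunity comparison "
                        "(missing DP or non-DP pair)", pid)
    if not frames:
        return pd.DataFrame()
    return pd.concat([f for f in frames if not f.empty], ignore_index=True)


def build_report(summaries: Sequence[ParticipantSummary],
                 day_metrics: Sequence[DayMetrics],
                 within_between, association, last_meal,
                 opportunities: pd.DataFrame) -> dict:
    """Cohort-level report; every entry is recomputable from the per-day
    outputs."""
    analytic = [s for s in summaries if not s.excluded]
    valid_days = [d for d in day_metrics if d.valid]
    deltas = np.array([d.delta_glucose for d in valid_days], dtype=float)
    dp_pcts = np.array([s.dp_percent for s in analytic], dtype=float)
    report = {
        "participants_enrolled": len(summaries),
        "participants_analytic": len(analytic),
        "participants_excluded_no_valid_days": sum(s.excluded for s in summaries),
        "days_observed": int(sum(s.n_days_observed for s in summaries)),
        "days_valid": len(valid_days),
        "days_dp": int(sum(1 for d in valid_days if d.dp_day)),
        "participants_with_any_dp_day": int(sum(1 for s in analytic if s.n_dp_days > 0)),
        "participants_with_dp_on_half_of_days": int(
            sum(1 for s in analytic if s.dp_percent is not None and s.dp_percent >= 50.0)),
        "pct_participants_with_any_dp_day": (
            100.0 * sum(1 for s in analytic if s.n_dp_days > 0) / len(analytic)
            if analytic else None),
        "dp_percent_mean": float(np.mean(dp_pcts)) if len(dp_pcts) else None,
        "dp_percent_sd": float(np.std(dp_pcts, ddof=1)) if len(dp_pcts) > 1 else None,
        "delta_glucose_mean": float(np.mean(deltas)) if len(deltas) else None,
        "delta_glucose_sd": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else None,
    }
    if within_between is not None:
        report["within_effect"] = within_between.within.estimate
        report["within_effect_ci"] = [within_between.within.ci_low,
                                      within_between.within.ci_high]
        report["within_effect_p"] = within_between.within.p_value
        report["between_effect"] = within_between.between.estimate
        report["between_effect_ci"] = [within_between.between.ci_low,
                                       within_between.between.ci_high]
        report["between_effect_p"] = within_between.between.p_value
    if association is not None:
        report["delta_prebreakfast_correlation"] = association.correlation
        report["delta_prebreakfast_correlation_ci"] = [association.ci_low,
                                                       association.ci_high]
        report["delta_prebreakfast_r_squared"] = association.r_squared
        report["delta_prebreakfast_p"] = association.p_value
    if last_meal is not None:
        report["last_meal_prebreakfast_slope"] = last_meal.prebreakfast.slope.estimate
        report["last_meal_prebreakfast_p"] = last_meal.prebreakfast.slope.p_value
        report["last_meal_delta_slope"] = last_meal.delta.slope.estimate
        report["last_meal_delta_p"] = last_meal.delta.slope.p_value
    if not opportunities.empty:
        report["mean_opportunities_dp_pair_threshold"] = float(
            opportunities["n_opportunities_dp_pair"].mean())
        report["mean_opportunities_nondp_pair_threshold"] = float(
            opportunities["n_opportunities_nondp_pair"].mean())
        report["mean_opportunity_difference"] = float(
            opportunities["difference"].mean())
    return report


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _report_text(report: dict) -> str:
    lines = ["Dawn-phenomenon cohort report", "=" * 29, ""]

    def fmt(v):
        if v is None:
            return "n/a"
        if isinstance(v, float):
            return f"{v:.2f}"
        if isinstance(v, list):
            return "[" + ", ".join(f"{x:.2f}" for x in v) + "]"
        return str(v)

    for key, value in report.items():
        lines.append(f"{key}: {fmt(value)}")
    lines.append("")
    return "\n".join(lines)


def analyze_cohort(traces: Sequence[GlucoseTrace],
                   diaries: Sequence[MealDiaryDay],
                   config: PipelineConfig | None = None) -> PipelineResult:
    """Run scoring, GGE and inference on in-memory traces and diaries."""
    config = config or PipelineConfig()
    config.validate()

    try:
        day_metrics = score_cohort(traces, diaries, config)
        summaries = summarize_cohort(day_metrics)
    except DawnMetricsError as exc:
        raise PipelineStageError("score", str(exc)) from exc

    days_by_pid: dict[str, list[DayMetrics]] = {}
    for d in day_metrics:
        days_by_pid.setdefault(d.participant_id, []).append(d)

    try:
        thresholds = _threshold_table(days_by_pid)
        opportunities = _opportunity_table(days_by_pid, traces, diaries,
                                           config.smoothing_width)
    except DawnMetricsError as exc:
        raise PipelineStageError("gge", str(exc)) from exc

    within_between = association = last_meal = None
    try:
        within_between = fit_within_between(day_metrics)
    except DegenerateDesignError as exc:
        logger.warning("within/between model not estimable: %s", exc)
    except DawnMetricsError as exc:
        raise PipelineStageError("inference/within_between", str(exc)) from exc
    try:
        association = fit_association(day_metrics)
    except DawnMetricsError as exc:
        logger.warning("association not estimable: %s", exc)
    try:
        last_meal = fit_last_meal_effects(day_metrics, diaries)
    except DegenerateDesignError as exc:
        logger.warning("last-meal models not estimable: %s", exc)
    except DawnMetricsError as exc:
        raise PipelineStageError("inference/last_meal", str(exc)) from exc
    mealtime = mealtime_summary(day_metrics, diaries, traces)

    report = build_report(summaries, day_metrics, within_between, association,
                          last_meal, opportunities)
    return PipelineResult(day_metrics, summaries, thresholds, opportunities,
                          within_between, association, last_meal, mealtime,
                          report)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_day_metrics(result.day_metrics, out / "day_metrics.csv")
    summaries_frame(result.summaries).to_csv(
        out / "participant_summary.csv", index=False, float_format="%.4f")
    result.thresholds.to_csv(out / "thresholds.csv", index=False,
                             float_format="%.4f")
    result.opportunities.to_csv(out / "opportunities.csv", index=False,
                                float_format="%.4f")
    result.mealtime.to_csv(out / "mealtime_summary.csv", index=False,
                           float_format="%.4f")

    def dump(obj, name):
        payload = None if obj is None else _round_floats(dataclasses.asdict(obj))
        (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                           default=str) + "\n")

    dump(result.within_between, "within_between.json")
    dump(result.association, "association.json")
    dump(result.last_meal, "last_meal.json")
    (out / "report.json").write_text(
        json.dumps(_round_floats(result.report), indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(_report_text(_round_floats(result.report)))


def run_pipeline(cgm_path: str | Path, diary_path: str | Path,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Full pipeline from files on disk; optionally writes the report bundle.

    Deterministic: identical inputs and configuration produce byte-identical
    outputs.
    """
    try:
        traces = dio.read_cgm(cgm_path)
        diaries = dio.read_meal_diary(diary_path)
    except DawnMetricsError as exc:
        raise PipelineStageError("ingest", str(exc)) from exc
    result = analyze_cohort(traces, diaries, config)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result
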