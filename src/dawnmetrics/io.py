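"""Reading and writing the pipeline's tabular text formats.

CGM file: ``participant_id,timestamp,glucose_mg_dl`` with ISO-8601 minute
timestamps (``YYYY-MM-DDTHH:MM``). Meal diary:
``participant_id,date,breakfast_time,lunch_time,dinner_time,last_meal_time,
overnight_eating_times`` where clock times are ``HH:MM`` (empty when not
reported) and overnight events are semicolon-separated. These match common
CGM exports after trivial reshaping; proprietary formats are out of scope.
"""

from __future__ import annotations

import logging
from datetime import date as Date, datetime, time as Time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IngestError
from .types import (DayMetrics, GlucoseTrace, GroundTruth, MealDiaryDay,
                    metrics_frame)

logger = logging.getLogger(__name__)

CGM_COLUMNS = ["participant_id", "timestamp", "glucose_mg_dl"]
DIARY_COLUMNS = ["participant_id", "date", "breakfast_time", "lunch_time",
                 "dinner_time", "last_meal_time", "overnight_eating_times"]


# --------------------------------------------------------------------------
# CGM traces

def read_cgm(path: str | Path) -> list[GlucoseTrace]:
    """Read CGM traces, one :class:`GlucoseTrace` per participant.

    Rows are sorted by time within participant; duplicate (participant,
    timestamp) rows collapse to their mean with a logged warning. Unparseable
    timestamps or non-numeric/out-of-range glucose raise :class:`IngestError`
    citing the 1-based line number. An empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"CGM file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing CGM columns {missing}")
    if df.empty:
        logger.warning("CGM file %s contains a header but no rows", path)
        return []

    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = int(lines[ts.isna().to_numpy()][0])
        raise IngestError(f"{path}: unparseable timestamp on line {bad}")
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    if glucose.isna().any():
        bad = int(lines[glucose.isna().to_numpy()][0])
        raise IngestError(f"{path}: non-numeric glucose on line {bad}")
    out_of_range = (glucose < 20.0) | (glucose > 600.0)
    if out_of_range.any():
        bad = int(lines[out_of_range.to_numpy()][0])
        raise IngestError(
            f"{path}: glucose outside [20, 600] mg/dL on line {bad}")

    tidy = pd.DataFrame({
        "participant_id": df["participant_id"].astype(str),
        "timestamp": ts,
        "glucose": glucose.astype(float),
    })
    n_before = len(tidy)
    tidy = (tidy.groupby(["participant_id", "timestamp"], as_index=False, sort=True)
            .agg(glucose=("glucose", "mean")))
    if len(tidy) < n_before:
        logger.warning("CGM file %s: collapsed %d duplicate (participant, timestamp) "
                       "rows to their mean", path, n_before - len(tidy))

    traces = []
    for pid, grp in tidy.groupby("participant_id", sort=True):
        readings = (grp[["timestamp", "glucose"]]
                    .sort_values("timestamp")
                    .reset_index(drop=True))
        traces.append(GlucoseTrace(participant_id=str(pid), readings=readings))
    return traces


def write_cgm(traces: list[GlucoseTrace], path: str | Path) -> None:
    """Write traces in the canonical CGM format (glucose to 0.01 mg/dL)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(CGM_COLUMNS) + "\n")
        for trace in traces:
            ts = trace.readings["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
            for t, g in zip(ts, trace.readings["glucose"]):
                fh.write(f"{trace.participant_id},{t},{g:.2f}\n")


# --------------------------------------------------------------------------
# meal diaries

def _parse_time(value, path, line, column) -> Time | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return datetime.strptime(str(value).strip(), "%H:%M").time()
    except ValueError:
        raise IngestError(
            f"{path}: malformed {column} {value!r} on line {line}") from None


def read_meal_diary(path: str | Path) -> list[MealDiaryDay]:
    """Read a meal diary, one record per participant-date.

    Duplicate participant-date rows raise; malformed clock times raise with
    the line number. Any eating event in [00:00, 06:00) — listed overnight
    event or meal time — marks the day as overnight eating.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"meal diary not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing diary columns {missing}")
    if df.empty:
        logger.warning("meal diary %s contains a header but no rows", path)
        return []

    records: list[MealDiaryDay] = []
    seen: set[tuple[str, Date]] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2
        pid = str(row["participant_id"])
        try:
            day = Date.fromisoformat(str(row["date"]).strip())
        except ValueError:
            raise IngestError(f"{path}: malformed date {row['date']!r} on line {line}") from None
        if (pid, day) in seen:
            raise IngestError(
                f"{path}: duplicate record for participant {pid!r} on {day} (line {line})")
        seen.add((pid, day))
        overnight = [
            _parse_time(v, path, line, "overnight_eating_times")
            for v in str(row["overnight_eating_times"]).split(";") if v.strip()
        ]
        records.append(MealDiaryDay(
            participant_id=pid,
            date=day,
            breakfast_time=_parse_time(row["breakfast_time"], path, line, "breakfast_time"),
            lunch_time=_parse_time(row["lunch_time"], path, line, "lunch_time"),
            dinner_time=_parse_time(row["dinner_time"], path, line, "dinner_time"),
            last_meal_time=_parse_time(row["last_meal_time"], path, line, "last_meal_time"),
            overnight_times=overnight,
        ))
    records.sort(key=lambda r: (r.participant_id, r.date))
    return records


def _fmt_time(t: Time | None) -> str:
    return "" if t is None else t.strftime("%H:%M")


def write_meal_diary(diaries: list[MealDiaryDay], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(DIARY_COLUMNS) + "\n")
        for d in sorted(diaries, key=lambda r: (r.participant_id, r.date)):
            overnight = ";".join(t.strftime("%H:%M") for t in d.overnight_times)
            fh.write(",".join([
                d.participant_id, d.date.isoformat(),
                _fmt_time(d.breakfast_time), _fmt_time(d.lunch_time),
                _fmt_time(d.dinner_time), _fmt_time(d.last_meal_time),
                overnight,
            ]) + "\n")


# --------------------------------------------------------------------------
# ground truth and scored outputs

def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write generator ground truth: per-day and per-participant tables plus
    the injected effects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    days = truth.days.copy()
    days["date"] = days["date"].map(lambda d: d.isoformat())
    days.to_csv(out / "ground_truth_days.csv", index=False, float_format="%.6f")
    truth.participants.to_csv(out / "ground_truth_participants.csv",
                              index=False, float_format="%.6f")
    pd.DataFrame([{"within_effect": truth.within_effect,
                   "between_effect": truth.between_effect}]
                 ).to_csv(out / "ground_truth_effects.csv", index=False,
                          float_format="%.6f")


def write_day_metrics(days: list[DayMetrics], path: str | Path) -> None:
    df = metrics_frame(days)
    df["date"] = df["date"].map(lambda d: d.isoformat())
    df.to_csv(Path(path), index=False, float_format="%.4f")


def read_day_metrics(path: str | Path) -> list[DayMetrics]:
    """Read back a ``day_metrics.csv`` written by :func:`write_day_metrics`."""
    df = pd.read_csv(path)

    def _opt(v):
        return None if pd.isna(v) else float(v)

    days = []
    for _, row in df.iterrows():
        valid = bool(row["valid"])
        days.append(DayMetrics(
            participant_id=str(row["participant_id"]),
            date=Date.fromisoformat(row["date"]),
            valid=valid,
            invalid_reason=None if pd.isna(row["invalid_reason"]) else str(row["invalid_reason"]),
            nocturnal_nadir=_opt(row["nocturnal_nadir"]),
            nadir_time=(None if pd.isna(row["nadir_time"])
                        else datetime.strptime(row["nadir_time"], "%H:%M").time()),
            prebreakfast_glucose=_opt(row["prebreakfast_glucose"]),
            prebreakfast_source=(None if pd.isna(row["prebreakfast_source"])
                                 else str(row["prebreakfast_source"])),
            glucose_6am=_opt(row["glucose_6am"]),
            delta_glucose=_opt(row["delta_glucose"]) if valid else None,
            dp_day=(bool(row["dp_day"]) if valid and not pd.isna(row["dp_day"]) else None),
        ))
    return days
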