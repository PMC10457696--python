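"""Shared fixtures: hand-built micro-traces and a simulated cohort."""

from datetime import date as Date, time as Time

import numpy as np
import pandas as pd
import pytest

from dawnmetrics import (GlucoseTrace, MealDiaryDay, SimulationConfig,
                         simulate_cohort)

DAY = Date(2021, 6, 1)


def make_trace(pid: str, day: Date, minutes, glucose) -> GlucoseTrace:
    """Trace from minutes-since-midnight offsets on one calendar day."""
    start = pd.Timestamp(day)
    ts = start + pd.to_timedelta(np.asarray(minutes, dtype=float), unit="m")
    return GlucoseTrace(pid, pd.DataFrame({"timestamp": ts,
                                           "glucose": np.asarray(glucose, float)}))


def make_diary(pid: str, day: Date, breakfast=None, last=None, lunch=None,
               dinner=None, overnight=()) -> MealDiaryDay:
    def t(v):
        if v is None or isinstance(v, Time):
            return v
        h = int(v)
        return Time(h, int(round((v - h) * 60)))
    return MealDiaryDay(participant_id=pid, date=day,
                        breakfast_time=t(breakfast), lunch_time=t(lunch),
                        dinner_time=t(dinner), last_meal_time=t(last),
                        overnight_times=[t(v) for v in overnight])


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale cohort under default conditions (fixed seed)."""
    cfg = SimulationConfig(rng_seed=1234)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimulationConfig(rng_seed=1234, sensor_noise_sd=0.0)
    return simulate_cohort(cfg)
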