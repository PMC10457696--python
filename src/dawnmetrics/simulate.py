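"""Synthetic CGM cohort generator with known dawn-phenomenon ground truth.

The generator emulates the structure the scoring pipeline assumes, one
participant-day at a time:

* a piecewise-linear diurnal mean curve — evening decline into the night,
  a nocturnal nadir between roughly 01:00 and 05:30, a linear dawn rise to
  the prebreakfast reading, a daytime plateau and an evening return;
* meal-triggered excursions with a gamma-like rise/decay shape after
  breakfast, lunch, dinner and any overnight eating event;
* white (optionally AR(1)) sensor noise and 0.01 mg/dL quantization.

Dawn-phenomenon status is a per-day Bernoulli draw from a per-person
probability; on DP days the injected rise is drawn above the 20 mg/dL label
boundary and below it otherwise, so labels are exact by construction.
Prebreakfast glucose is generated directly from the within/between
mixed-model equation

    y_ij = g0 + (gB - gW) * xbar_i + gW * x_ij + u_i + d_ij

(x_ij the day's DP indicator, xbar_i the participant's realized valid-day DP
proportion), and the nocturnal nadir is back-computed as y_ij minus the
injected rise. Fitting the within/between model to the scored data therefore
recovers gW and gB without attenuation.

The dawn rise is anchored at the exact grid reading the scorer selects (the
last reading at or before min(breakfast, 10:00)), so with sensor noise off
the scored ∂ glucose equals the injected magnitude up to quantization.
"""

from __future__ import annotations

import math
from datetime import datetime, time as Time, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .types import GlucoseTrace, GroundTruth, MealDiaryDay, hours_to_time

__all__ = ["simulate_cohort"]


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(a, b) for a mean/SD on (0, 1)."""
    if not 0 < mean < 1:
        raise ValueError("beta mean must be in (0, 1)")
    max_var = mean * (1 - mean)
    var = min(sd * sd, 0.98 * max_var)
    nu = max_var / var - 1.0
    return mean * nu, (1 - mean) * nu


def _trunc_normal(rng, mean, sd, low, high, size=None):
    if sd == 0:
        val = np.clip(mean, low, high)
        return np.full(size, val) if size is not None else float(val)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _excursion(grid_min: np.ndarray, t_meal_min: float, amplitude: float,
               decay_min: float) -> np.ndarray:
    """Meal excursion: zero at the meal time, peak ``amplitude`` after
    ``decay_min`` minutes, exponential relaxation afterwards."""
    dt = grid_min - t_meal_min
    s = np.where(dt > 0, dt / decay_min, 0.0)
    return amplitude * s * np.exp(1.0 - s) * (dt > 0)


def _day_noise(rng, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if rho == 0:
        return rng.normal(0.0, sd, size=n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[GlucoseTrace], list[MealDiaryDay], GroundTruth]:
    """Generate CGM traces, meal diaries and ground truth for one cohort.

    Returns one :class:`GlucoseTrace` per participant, one
    :class:`MealDiaryDay` per participant-day, and a :class:`GroundTruth`
    holding the injected dawn-rise magnitude and DP label for every day plus
    the within/between effects used. Identical config (including
    ``rng_seed``) reproduces the output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    interval = config.sampling_interval
    grid = np.arange(0, 1440, interval, dtype=float)  # minutes since midnight
    nocturnal_mask = grid < 360.0

    gW, gB = config.within_effect, config.between_effect
    thr = config.dp_threshold
    guard = config.magnitude_guard

    traces: list[GlucoseTrace] = []
    diaries: list[MealDiaryDay] = []
    truth_days: list[dict] = []
    truth_people: list[dict] = []

    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        always_overnight = i < config.overnight_every_day_participants

        if config.dp_probability_sd > 0:
            a, b = _beta_params(config.dp_probability_mean, config.dp_probability_sd)
            p_dp = float(rng.beta(a, b))
        else:
            p_dp = config.dp_probability_mean
        u_i = float(rng.normal(0.0, config.baseline_glucose_sd))
        n_days = int(np.clip(
            round(rng.normal(config.days_per_participant_mean,
                             config.days_per_participant_sd)),
            config.days_min, config.days_max))
        logs_lunch_dinner = bool(rng.random() < config.lunch_dinner_logging_probability)

        # ---- per-day draws (all up front so xbar is known before curves) ----
        bk = _trunc_normal(rng, config.breakfast_time_mean, config.breakfast_time_sd,
                           6.25, 11.5, size=n_days)
        lunch = rng.normal(config.lunch_time_mean, config.lunch_time_sd, size=n_days)
        dinner = rng.normal(config.dinner_time_mean, config.dinner_time_sd, size=n_days)
        last = rng.normal(config.last_meal_time_mean, config.last_meal_time_sd, size=n_days)
        lunch = np.maximum(lunch, bk + 1.5)
        dinner = np.maximum(dinner, lunch + 2.0)
        last = np.clip(np.maximum(last, dinner), None, 23.8)
        # quantize eating times to the minute so curves match the diary exactly
        bk, lunch, dinner, last = (np.round(t * 60.0) / 60.0
                                   for t in (bk, lunch, dinner, last))

        x = rng.random(n_days) < p_dp
        overnight = np.full(n_days, True) if always_overnight else (
            rng.random(n_days) < config.overnight_eating_probability)
        overnight_hour = np.round(rng.uniform(0.75, 5.0, size=n_days) * 60.0) / 60.0
        miss_bk = rng.random(n_days) < config.breakfast_missing_probability
        miss_last = rng.random(n_days) < config.last_meal_missing_probability
        valid = ~overnight & ~miss_bk & ~miss_last

        magnitude = np.where(
            x,
            _trunc_normal(rng, config.dp_magnitude_mean, config.dp_magnitude_sd,
                          thr + guard, thr + 8 * max(config.dp_magnitude_sd, 1.0),
                          size=n_days),
            _trunc_normal(rng, config.nondp_magnitude_mean, config.nondp_magnitude_sd,
                          0.0, thr - guard, size=n_days),
        )
        day_dev = rng.normal(0.0, config.day_noise_sd, size=n_days)
        t_nadir_h = _trunc_normal(rng, config.nadir_time_mean, config.nadir_time_sd,
                                  1.0, 5.25, size=n_days)
        amp = np.clip(rng.normal(config.meal_excursion_amplitude_mean,
                                 config.meal_excursion_amplitude_sd,
                                 size=(n_days, 4)), 5.0, None)

        xbar = float(x[valid].mean()) if valid.any() else float(x.mean())

        ts_all: list[np.ndarray] = []
        g_all: list[np.ndarray] = []
        for d in range(n_days):
            day = config.start_date + timedelta(days=d)
            y_target = (config.baseline_glucose_mean + (gB - gW) * xbar
                        + gW * float(x[d]) + u_i + float(day_dev[d]))
            nadir = y_target - float(magnitude[d])

            t_nadir = round(t_nadir_h[d] * 60.0 / interval) * interval
            bk_min = float(bk[d]) * 60.0
            t_anchor = math.floor(min(bk_min, 600.0) / interval) * interval

            anchors_t = [0.0, t_nadir, t_anchor, bk_min, 1200.0, 1440.0]
            anchors_v = [nadir + config.nocturnal_drop, nadir,
                         y_target, y_target, y_target,
                         nadir + config.nocturnal_drop]
            # drop any non-increasing anchor times (e.g. breakfast on-grid)
            at, av = [anchors_t[0]], [anchors_v[0]]
            for t, v in zip(anchors_t[1:], anchors_v[1:]):
                if t > at[-1]:
                    at.append(t)
                    av.append(v)
            curve = np.interp(grid, at, av)

            curve += _excursion(grid, bk_min, amp[d, 0], config.meal_excursion_decay)
            curve += _excursion(grid, lunch[d] * 60.0, amp[d, 1], config.meal_excursion_decay)
            curve += _excursion(grid, dinner[d] * 60.0, amp[d, 2], config.meal_excursion_decay)
            if last[d] - dinner[d] > 0.5:  # distinct evening snack
                curve += _excursion(grid, last[d] * 60.0, 0.5 * amp[d, 3],
                                    config.meal_excursion_decay)
            if overnight[d]:
                curve += _excursion(grid, overnight_hour[d] * 60.0, amp[d, 3],
                                    config.meal_excursion_decay)
            curve = np.clip(curve, config.glucose_floor, config.glucose_ceiling)

            # effective (post-clip) ground truth, from the noise-free curve
            noct = curve[nocturnal_mask]
            idx_nadir = int(np.argmin(noct))
            nadir_eff = float(noct[idx_nadir])
            idx_pb = int(t_anchor / interval)
            pb_eff = float(curve[idx_pb])
            delta_eff = max(pb_eff - nadir_eff, 0.0)

            noise = _day_noise(rng, len(grid), config.sensor_noise_sd,
                               config.sensor_noise_ar1)
            glucose = np.round(np.clip(curve + noise, 25.0, 575.0), 2)

            keep = np.ones(len(grid), dtype=bool)
            if config.reading_dropout > 0:
                keep = rng.random(len(grid)) >= config.reading_dropout
                if not keep.any():
                    keep[0] = True

            day_start = np.datetime64(datetime.combine(day, Time(0, 0)), "ns")
            ts_all.append(day_start + (grid[keep] * 60e9).astype("timedelta64[ns]"))
            g_all.append(glucose[keep])

            diaries.append(MealDiaryDay(
                participant_id=pid,
                date=day,
                breakfast_time=None if miss_bk[d] else hours_to_time(bk[d]),
                lunch_time=hours_to_time(lunch[d]) if logs_lunch_dinner else None,
                dinner_time=hours_to_time(dinner[d]) if logs_lunch_dinner else None,
                last_meal_time=None if miss_last[d] else hours_to_time(last[d]),
                overnight_times=[hours_to_time(overnight_hour[d])] if overnight[d] else [],
            ))
            truth_days.append({
                "participant_id": pid,
                "date": day,
                "dp_true": bool(delta_eff >= thr),
                "magnitude": delta_eff,
                "nadir_true": nadir_eff,
                "prebreakfast_true": pb_eff,
                "expected_valid": bool(valid[d]),
            })

        readings = pd.DataFrame({
            "timestamp": pd.DatetimeIndex(np.concatenate(ts_all)),
            "glucose": np.concatenate(g_all),
        })
        traces.append(GlucoseTrace(participant_id=pid, readings=readings))
        truth_people.append({
            "participant_id": pid,
            "dp_probability": p_dp,
            "baseline_offset": u_i,
            "n_days": n_days,
            "dp_proportion": xbar,
        })

    truth = GroundTruth(
        days=pd.DataFrame(truth_days),
        participants=pd.DataFrame(truth_people),
        within_effect=gW,
        between_effect=gB,
    )
    return traces, diaries, truth
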