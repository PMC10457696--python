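"""Configuration objects for simulation and scoring.

Defaults encode the study conditions the package emulates: ~22 adults with
non-insulin-treated type 2 diabetes wearing a 5-minute CGM for 6-11 days,
roughly half of valid days showing a dawn rise of >= 20 mg/dL, breakfast near
08:15 and the last meal near 20:30, and one participant who eats overnight
every day (and therefore contributes no valid days).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from datetime import date as Date
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic CGM + meal-diary generator.

    All glucose quantities are mg/dL, times are decimal clock hours, and the
    sampling interval is minutes. ``within_effect`` / ``between_effect`` are
    the mixed-model coefficients the generator injects into prebreakfast
    glucose (per DP day and per unit DP proportion respectively).

    The conditional dawn-rise distributions (``dp_magnitude_*`` on DP days,
    ``nondp_magnitude_*`` otherwise) are a modelling choice: only the overall
    mean ~24 (SD ~13) mg/dL is anchored, so the split between components is
    set to reproduce those moments with ~51% DP days.
    """

    n_participants: int = 22
    days_per_participant_mean: float = 10.5
    days_per_participant_sd: float = 1.1
    days_min: int = 6
    days_max: int = 11
    sampling_interval: int = 5
    start_date: Date = Date(2021, 6, 1)

    # prebreakfast-glucose model (mg/dL)
    baseline_glucose_mean: float = 105.0   # intercept at DP proportion 0
    baseline_glucose_sd: float = 15.0      # between-person random intercept SD
    day_noise_sd: float = 12.0             # within-person day-to-day SD
    within_effect: float = 12.0            # mg/dL per DP day
    between_effect: float = 54.0           # mg/dL per unit DP proportion

    # dawn-phenomenon structure
    dp_probability_mean: float = 0.51      # per-person Beta mean
    dp_probability_sd: float = 0.272       # per-person Beta SD (0 -> constant)
    dp_magnitude_mean: float = 33.0        # dawn rise on DP days (truncated >= 20)
    dp_magnitude_sd: float = 9.0
    nondp_magnitude_mean: float = 14.5     # dawn rise on non-DP days (truncated < 20)
    nondp_magnitude_sd: float = 8.0
    dp_threshold: float = 20.0             # label boundary, mg/dL
    magnitude_guard: float = 0.05          # keep draws this far from the boundary

    # diurnal shape
    nocturnal_drop: float = 18.0           # midnight glucose above the nadir
    nadir_time_mean: float = 3.5           # clock hours
    nadir_time_sd: float = 0.75
    meal_excursion_amplitude_mean: float = 40.0
    meal_excursion_amplitude_sd: float = 12.0
    meal_excursion_decay: float = 45.0     # minutes to excursion peak

    # sensor model
    sensor_noise_sd: float = 1.5           # mg/dL per reading (smoothed-output scale)
    sensor_noise_ar1: float = 0.0          # AR(1) coefficient, 0 = white noise
    reading_dropout: float = 0.0           # per-reading missingness

    # diary behaviour
    breakfast_time_mean: float = 8.28      # 08:17
    breakfast_time_sd: float = 1.07
    lunch_time_mean: float = 12.6
    lunch_time_sd: float = 0.7
    dinner_time_mean: float = 18.6
    dinner_time_sd: float = 0.9
    last_meal_time_mean: float = 20.55     # 20:33
    last_meal_time_sd: float = 1.1
    lunch_dinner_logging_probability: float = 0.7   # per participant
    overnight_eating_probability: float = 0.12      # per day
    overnight_every_day_participants: int = 1       # these eat overnight daily
    breakfast_missing_probability: float = 0.05     # per day
    last_meal_missing_probability: float = 0.05

    rng_seed: int = 0

    # physiologic clamp applied to the noise-free curve (kept inside the
    # sensor reporting range so ingest validation round-trips)
    glucose_floor: float = 40.0
    glucose_ceiling: float = 400.0

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (1 <= self.days_min <= self.days_max):
            raise ConfigError("days_min must satisfy 1 <= days_min <= days_max")
        if self.sampling_interval < 1 or 1440 % self.sampling_interval != 0:
            raise ConfigError("sampling_interval must be a positive divisor of 1440")
        for name in ("days_per_participant_sd", "baseline_glucose_sd", "day_noise_sd",
                     "dp_probability_sd", "dp_magnitude_sd", "nondp_magnitude_sd",
                     "nadir_time_sd", "meal_excursion_amplitude_sd", "sensor_noise_sd",
                     "breakfast_time_sd", "lunch_time_sd", "dinner_time_sd",
                     "last_meal_time_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("dp_probability_mean", "overnight_eating_probability",
                     "breakfast_missing_probability", "last_meal_missing_probability",
                     "lunch_dinner_logging_probability", "reading_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1.0 < self.sensor_noise_ar1 < 1.0:
            raise ConfigError("sensor_noise_ar1 must lie in (-1, 1)")
        if self.dp_threshold <= 0:
            raise ConfigError("dp_threshold must be > 0")
        if not 0 <= self.overnight_every_day_participants <= self.n_participants:
            raise ConfigError(
                "overnight_every_day_participants must lie in [0, n_participants]")
        if self.meal_excursion_decay <= 0:
            raise ConfigError("meal_excursion_decay must be > 0")
        if not self.glucose_floor < self.glucose_ceiling:
            raise ConfigError("glucose_floor must be < glucose_ceiling")


@dataclass
class PipelineConfig:
    """Scoring and analysis settings; defaults reproduce the published rules.

    The nocturnal window is half-open [00:00, 06:00); the breakfast window is
    [06:00, 10:00] with the 10:00 fallback inclusive; a ∂ glucose of
    ``dp_threshold`` mg/dL or more marks a dawn-phenomenon day.
    """

    dp_threshold: float = 20.0
    nocturnal_window: tuple[float, float] = (0.0, 6.0)    # clock hours
    breakfast_window: tuple[float, float] = (6.0, 10.0)   # clock hours
    pair_rule: str = "first-available"
    smoothing_width: int = 0          # moving-average pre-filter, 0 = off
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.nocturnal_window
        blo, bhi = self.breakfast_window
        if not 0 <= lo < hi <= 24:
            raise ConfigError("nocturnal_window bounds must satisfy 0 <= start < end <= 24")
        if not lo < hi <= blo < bhi <= 24:
            raise ConfigError("breakfast_window must follow the nocturnal window")
        if self.dp_threshold <= 0:
            raise ConfigError("dp_threshold must be > 0")
        if self.pair_rule not in {"first-available", "any-pair", "both-DP", "both-non-DP"}:
            raise ConfigError(f"unknown pair_rule {self.pair_rule!r}")
        if self.smoothing_width < 0:
            raise ConfigError("smoothing_width must be >= 0")


def _coerce(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is SimulationConfig and "start_date" in kwargs and isinstance(kwargs["start_date"], str):
        kwargs["start_date"] = Date.fromisoformat(kwargs["start_date"])
    for key in ("nocturnal_window", "breakfast_window"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    obj = cls(**kwargs)
    obj.validate()
    return obj


def load_simulation_config(path: str | Path | None = None, **overrides) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML, applying keyword overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return _coerce(SimulationConfig, data)


def load_pipeline_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, applying keyword overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return _coerce(PipelineConfig, data)


def config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    if isinstance(d.get("start_date"), Date):
        d["start_date"] = d["start_date"].isoformat()
    return d
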