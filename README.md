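# dawnmetrics

Dawn-phenomenon analysis of continuous glucose monitoring (CGM) data, built
for studying whether glucose-guided eating (GGE) thresholds are workable in
non-insulin-treated type 2 diabetes.

The **dawn phenomenon (DP)** is the early-morning glucose rise from the
nocturnal nadir. GGE permits eating only when hungry *and* when glucose is
below a personalized threshold — the mean of two consecutive morning
preprandial values — so mornings inflated by DP can make such thresholds too
permissive (derived on DP mornings) or too strict (derived on non-DP
mornings). `dawnmetrics` implements the full analysis chain:

* **Scoring** — per participant-day: valid-day determination (reported
  breakfast + last meal, no eating between midnight and 6 AM), nocturnal
  nadir (minimum reading in [00:00, 06:00)), prebreakfast glucose (last
  reading before breakfast in [06:00, 10:00], 10:00 fallback),
  **∂ glucose = max(prebreakfast − nadir, 0)**, and the DP flag
  (∂ ≥ 20 mg/dL).
* **GGE** — personalized thresholds from pairs of consecutive valid
  mornings (DP-pair / non-DP-pair / first available) and eating-opportunity
  counts: downward threshold crossings inside the eating window.
* **Inference** — the within/between-person mixed model
  `y_ij = γ0 + γB·x̄_i + γW·(x_ij − x̄_i) + u_i + ε_ij` of prebreakfast
  glucose on DP status (REML, Wald CIs), the day-level ∂–prebreakfast
  Pearson correlation (Fisher-z CI), next-day last-meal-timing models, and
  DP-stratified mealtime glucose summaries.
* **Simulation** — a synthetic CGM + meal-diary cohort generator with exact
  per-day ground truth (injected dawn rise, DP label, true γW/γB), emulating
  a ~22-person, 6–11 day cohort with ~51% DP days, mean ∂ ≈ 24 (SD 13)
  mg/dL, and one participant who eats overnight every night and is excluded
  from DP analyses.

## Worked example

```python
from dawnmetrics import (SimulationConfig, simulate_cohort, score_cohort,
                         fit_within_between, fit_association)

traces, diaries, truth = simulate_cohort(SimulationConfig(rng_seed=42))
days = score_cohort(traces, diaries)
fit = fit_within_between(days)
assoc = fit_association(days)
```

Running `python examples/04_mixed_models.py` (which does the above) prints:

```
within-person effect:  4.7 mg/dL (95% CI 0.1 to 9.3) [generator truth: 12]
between-person effect: 65.5 mg/dL per unit DP proportion (95% CI 36.2 to 94.7) [generator truth: 54]
∂ vs prebreakfast correlation: r = 0.44 (95% CI 0.31 to 0.56), R^2 = 0.20, n = 167 days
last-meal hour -> next-day prebreakfast: slope +0.20 mg/dL/h, p = 0.86
last-meal hour -> next-day ∂ glucose:    slope +0.48 mg/dL/h, p = 0.61
```

The within-person estimate says mornings after a DP night run higher than
the same person's non-DP mornings; the between-person estimate says people
who experience DP on every day would average ~54–65 mg/dL higher morning
glucose than people who never do. Any single 21-person cohort is noisy (this
seed's within estimate, 4.7, sits low; threshold misclassification from
sensor noise also attenuates it slightly) — the test suite verifies
calibration over 200 replicate cohorts. The last-meal slopes are null by
construction. Other entry points are shown in `examples/01...05`, and a thin
CLI mirrors the library:

```bash
dawnmetrics simulate --seed 7 --out cohort/
dawnmetrics run --cgm cohort/cgm.csv --diary cohort/diary.csv --out results/
```

`results/report.txt` then summarizes the cohort: enrolled vs analytic
participants, valid-day accounting, DP prevalence, mean ∂ glucose, model
fits and opportunity counts.

## Input formats

CGM: CSV with `participant_id,timestamp,glucose_mg_dl` (ISO-8601 minute
timestamps, mg/dL in [20, 600]). Meal diary: CSV with
`participant_id,date,breakfast_time,lunch_time,dinner_time,last_meal_time,
overnight_eating_times` (HH:MM, blanks for unreported, overnight events
semicolon-separated). Proprietary CGM exports need a one-off reshape to this
schema.

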