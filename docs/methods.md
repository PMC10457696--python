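# Methods

## Problem and scope

`dawnmetrics` analyzes the dawn phenomenon (DP) — the early-morning rise in
glucose from the nocturnal nadir — in continuous glucose monitoring (CGM)
data from adults with non-insulin-treated type 2 diabetes, and its
consequences for glucose-guided eating (GGE), a timed-eating paradigm in
which eating is permitted only when hungry and when glucose is below a
personalized threshold derived from two consecutive morning preprandial
values. The package implements day-level DP scoring, GGE threshold
derivation and eating-opportunity counting, within/between-person mixed
modelling, and a synthetic cohort generator with exact ground truth so that
every stage is testable without access to clinical data.

## Scoring rules

All windows are wall-clock local time; days are calendar dates.

* **Valid day** — the diary reports a breakfast (first meal or snack) and a
  last meal, and no eating event falls in [00:00, 06:00). The overnight
  window is half-open so it tiles exactly against the breakfast window.
* **Nocturnal nadir** — minimum reading in [00:00, 06:00); ties broken by
  earliest time (tie-break affects only the reported time, never ∂).
* **Prebreakfast (morning preprandial) glucose** — the last reading at or
  before breakfast within [06:00, 10:00]; if breakfast is after 10:00, the
  reading nearest 10:00 within half a sampling interval.
* **∂ glucose** = max(prebreakfast − nadir, 0). The zero floor applies when
  every nocturnal reading exceeds the prebreakfast level.
* **DP day** — ∂ glucose ≥ 20 mg/dL, threshold inclusive and configurable
  (`PipelineConfig.dp_threshold`) for Monnier-style sensitivity analyses.
* **Missing CGM coverage** in a required window demotes the day to invalid
  with a logged reason code rather than interpolating; validity is otherwise
  a property of the diary alone. A "6 AM glucose" (reading nearest 06:00) is
  reported for mealtime summaries but enters no inferential statistic.

Window arithmetic is done in exact minutes (`time_to_minutes`), not decimal
hours: `8 + 25/60` hours times 60 is one ulp below 505 minutes and silently
excludes an on-the-minute reading at the window edge.

## GGE thresholds and eating opportunities

A threshold is the arithmetic mean of the prebreakfast glucose on the first
pair of *calendar-adjacent* valid days satisfying the pair rule (`both-DP`,
`both-non-DP`, or first available); an intervening invalid day disqualifies
a pair. An eating opportunity on a day is a drop of the raw trace to or
below the threshold inside the inclusive eating window
[breakfast, last meal]: being at or below the threshold at the first
in-window reading counts once, and every subsequent downward crossing
(previous reading above, current at or below) counts once more. Whether the
study counted an initial below-threshold state is not decidable from the
published description; our rule is documented, not asserted as theirs. A
moving-average pre-filter is available (`smoothing_width`) but off by
default, since no smoothing is described for the original analysis.

**The episode count is not monotone in the threshold.** Raising the
threshold can merge two below-threshold episodes into one (trace
`[115, 125, 115]` has two opportunities at threshold 120 but one at 130),
and sensor noise fragments episodes, so per-day counts under a higher
threshold are often *lower*. The monotone quantities are the existence of an
opportunity and the time spent at or below the threshold; the package's
tests assert those, plus exact agreement with a brute-force crossing scan,
plus the cohort-level claim that DP-derived thresholds permit more
opportunities *on average*.

## Statistical models

The central model decomposes the DP effect on prebreakfast glucose
y<sub>ij</sub> (participant i, valid day j, DP indicator x<sub>ij</sub>):

y_ij = γ0 + γB·x̄_i + γW·(x_ij − x̄_i) + u_i + ε_ij

* x̄_i is the participant's DP proportion over valid days, entered on the
  [0, 1] scale so γB is the full never-DP → always-DP contrast in mg/dL (the
  published scaling is not stated; this choice is documented prominently).
* Estimation is REML via `statsmodels.MixedLM` with Wald 95% intervals and
  normal p-values. Small cohorts often put the random-intercept variance on
  the zero boundary, where the default optimizer may report non-convergence;
  the fit retries with `lbfgs`, `powell` and `cg` before raising.
* Degenerate designs (constant within-deviation, e.g. no DP days anywhere;
  constant DP proportion across participants; fewer than two participants
  with two valid days) raise explicit errors rather than returning a
  singular fit.

The ∂–prebreakfast association is a plain day-level Pearson correlation with
a Fisher-z 95% CI, deliberately ignoring within-person clustering so it
mirrors a day-level scatter (R² = r²); a cluster-robust day-level regression
slope is available as an option. Last-meal timing effects pair each diary
day's last-meal clock hour with the *next* day's prebreakfast glucose and ∂,
fitted as random-intercept mixed models. No multiple-testing adjustment is
applied. Mealtime summaries report mean (SD) of 6 AM, pre-breakfast,
pre-lunch and pre-dinner glucose and of breakfast/last-meal clock hours for
all observed days and for DP / non-DP valid days; empty strata are omitted,
never zero-filled.

## Synthetic cohort generator

Defaults encode the emulated study conditions: 22 participants (one of whom
eats overnight every day and therefore contributes no valid days, exercising
the exclusion rule), 6–11 wear days (mean 10.5, SD 1.1), 5-minute sampling,
breakfast ≈ 08:17 (SD ≈ 1:04), last meal ≈ 20:33 (SD ≈ 1:06), ~12%/day
overnight eating and ~5%/day missing breakfast or last-meal reports (chosen
so the valid fraction matches ≈ 8 valid days per ~10.5 worn).

Per participant: a DP probability p_i ~ Beta matched to mean 0.51, SD 0.272;
a random intercept u_i ~ N(0, 15²) mg/dL. Per day: a Bernoulli DP indicator
x_ij; an injected dawn rise drawn truncated-normal(33, 9) on [20.05, ∞) on
DP days and truncated-normal(14.5, 8) on [0, 19.95] otherwise. Only the
overall ∂ moments (mean ≈ 24, SD ≈ 13 mg/dL) are anchored by the emulated
cohort; the DP-conditional split is a modelling choice, and the 0.05 mg/dL
guard bands keep labels exact under the 0.01 mg/dL file quantization.

Prebreakfast glucose is generated *directly from the mixed-model equation*
using the realized valid-day proportion x̄_i (intercept 105 mg/dL, γW = 12,
γB = 54, day-level SD 12), and the nocturnal nadir is back-computed as
y − magnitude. The fitted model is therefore exactly the data-generating
model, so parameter-recovery tests probe the estimator rather than an
attenuation artifact. The diurnal curve is piecewise linear (midnight at
nadir + 18 mg/dL, nadir at ≈ 03:30, linear dawn rise anchored at the exact
grid reading the scorer will select, daytime plateau, evening decline), plus
meal excursions of the form A·(t/τ)·e^(1−t/τ) (A ≈ 40 mg/dL, τ = 45 min)
after breakfast, lunch, dinner, evening snacks and overnight events, plus
white sensor noise (AR(1) optional, off by default) and a physiologic clamp
to [40, 400] mg/dL. Ground truth records the *effective* (post-clamp)
magnitude and label, so truth remains exact even on clamped days. Eating
times are quantized to the minute before curve construction so the written
diary and the curve agree exactly.

`sensor_noise_sd` defaults to 1.5 mg/dL: factory-smoothed G6-style output
has small short-interval noise, and because the nadir is a minimum over ~72
readings, white reading noise biases scored ∂ upward by roughly 1.5σ — a
large σ would visibly distort every scored quantity.

### What the generator does not emulate

Sensor drift and calibration artifacts, compression lows, physiologic
glucose–insulin dynamics, daylight-saving transitions, diary misreporting
(times are exact by construction), and day-to-day autocorrelation of DP
status. Passing tests therefore demonstrate correctness of the *procedures*
under the stated statistical structure, not robustness to every failure mode
of real wearable data.

## Numerical and testing choices

* Determinism: a single `numpy` Generator seeded from the config; identical
  config ⇒ bit-identical traces, diaries and truth. Pipeline outputs use
  fixed float formatting, so reruns are byte-identical.
* Glucose is quantized to 0.01 mg/dL at write time and the generator rounds
  identically, so write → read round-trips reproduce in-memory objects
  exactly.
* With sensor noise off, scored ∂ equals the injected magnitude to ≤ 0.02
  mg/dL (quantization only) because the dawn-rise anchor coincides with the
  scorer's selected reading; DP labels agree with truth on 100% of valid
  days.
* With noise on, misclassification concentrates near the 20 mg/dL boundary.
  The scored-∂ error has RMSE ≈ 2.4 mg/dL at default noise (upward nadir
  bias ≈ 1.7 plus reading noise); Gaussian tails imply occasional flips just
  beyond any fixed multiple of that scale, so "all flips within 2×RMSE of
  20" holds for most but not every cohort. Boundary misclassification also
  attenuates the fitted within-person effect toward zero — an inherent
  property of threshold-based day classification, which is why
  estimator-recovery tests run with noise off.
* Problem sizes: scoring-oracle checks use 1,300 simulated days;
  opportunity-count checks 500 days × 5 thresholds; within/between recovery
  200 cohorts of 21 × 8 valid days; null calibration of the last-meal slope
  500 replicates; association recovery 60 replicates per ρ at n = 170 days.

## Known limitations

* Wald intervals with ~21 clusters are mildly anti-conservative (measured
  within-effect CI coverage ≈ 93–94% at nominal 95%).
* The between-person coefficient uses the observed valid-day DP proportion;
  with few days per person this proportion is itself noisy, and comparisons
  against an externally defined "true frequency" would show attenuation.
* Timestamps are naive local time; timezone declaration is accepted but no
  conversion is performed.
* Proprietary CGM export formats are not parsed; inputs are the documented
  CSV schemas.
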