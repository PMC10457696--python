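"""Score participant-days: validity, nocturnal nadir, ∂ glucose, DP flags.

A valid day has a reported breakfast and last meal and no eating between
midnight and 6 AM. ∂ glucose is the rise from the nocturnal nadir (minimum
reading in [00:00, 06:00)) to the prebreakfast reading; >= 20 mg/dL marks a
dawn-phenomenon (DP) day.
"""

from dawnmetrics import (SimulationConfig, metrics_frame, score_cohort,
                         simulate_cohort, summarize_cohort)

traces, diaries, _ = simulate_cohort(SimulationConfig(rng_seed=42))
days = score_cohort(traces, diaries)

df = metrics_frame(days)
print("first scored days of participant P02:")
cols = ["date", "valid", "nocturnal_nadir", "prebreakfast_glucose",
        "delta_glucose", "dp_day"]
print(df[df["participant_id"] == "P02"][cols].head(6).to_string(index=False))

print("\nper-participant summaries (first 5):")
for s in summarize_cohort(days)[:5]:
    pct = "excluded (0 valid days)" if s.excluded else f"DP on {s.dp_percent:.0f}% of valid days"
    print(f"  {s.participant_id}: {s.n_valid_days}/{s.n_days_observed} valid, {pct}")

# Each row is one participant-day; dp_day is only defined on valid days.
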