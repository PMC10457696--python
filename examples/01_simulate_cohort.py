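"""Generate a synthetic CGM cohort and inspect its ground truth.

The generator emulates a cohort of adults with non-insulin-treated type 2
diabetes wearing a 5-minute CGM for 6-11 days: diurnal glucose with a
nocturnal nadir, a dawn rise of >= 20 mg/dL on roughly half of days, meal
excursions, sensor noise, and one participant who eats overnight every day.
"""

from dawnmetrics import SimulationConfig, simulate_cohort

cfg = SimulationConfig(rng_seed=42)
traces, diaries, truth = simulate_cohort(cfg)

n_readings = sum(len(t) for t in traces)
print(f"participants: {len(traces)}, diary days: {len(diaries)}, "
      f"CGM readings: {n_readings}")

days = truth.days
print(f"ground-truth DP days: {days['dp_true'].sum()} of {len(days)} "
      f"({100 * days['dp_true'].mean():.1f}%)")
print(f"injected dawn rise, mean (SD): {days['magnitude'].mean():.1f} "
      f"({days['magnitude'].std():.1f}) mg/dL")
print(f"injected within-person effect: {truth.within_effect:.1f} mg/dL per DP day")
print(f"injected between-person effect: {truth.between_effect:.1f} mg/dL "
      f"per unit DP proportion")

# The dawn-rise magnitude is the rise from the nocturnal nadir to the
# prebreakfast reading on the noise-free curve; DP days are those at or
# above the 20 mg/dL threshold by construction.
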