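"""Generate a synthetic three-arm RTW trial cohort and inspect its structure.

The generator encodes the trial contrasts explicitly: monthly RTW hazard
ratios, monthly benefit-receipt odds ratios, intervention unit costs, and
absence-day shifts, all relative to the usual-case-management (UC) arm.
"""

from trialecon import generate_cohort, impose_missingness, trial_calibrated_config

cfg = trial_calibrated_config(seed=1)
cohort = impose_missingness(generate_cohort(cfg), cfg)

b = cohort.baseline
print(f"cohort: {cohort.n} participants, arms {cohort.arms()}")
print("\nArm means (EUR / days):")
print(b.groupby("arm")[["absence_days", "cost_absenteeism", "cost_total"]]
      .mean().round(0).to_string())
print("\nMissing values per column (MAR overlay):")
print(b.isna().sum()[lambda s: s > 0].to_string())
print("\nEach row is one participant; the long panel (id, month, "
      "absence_fraction, benefit_received) drives the survival and "
      "benefit-receipt analyses. Absenteeism cost is exactly absence days "
      "times the gender-stratified daily wage.")
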