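"""Bootstrap cost-effectiveness, CE-plane quadrants, CEAC, and ROI metrics.

Effects are sickness-absence days averted; absenteeism cost is excluded from
the cost side (the days themselves are the monetized outcome).
"""

from trialecon import (ce_analysis, generate_cohort, roi_analysis,
                       trial_calibrated_config)

cohort = generate_cohort(trial_calibrated_config(seed=5))

for r in ce_analysis(cohort, effect="days", B=2000, seed=5):
    print(f"{r.comparison}:")
    print(f"  delta C = EUR {r.delta_C:+.0f} "
          f"({r.delta_C_ci[0]:.0f} to {r.delta_C_ci[1]:.0f})")
    print(f"  delta E = {r.delta_E:+.1f} days averted "
          f"({r.delta_E_ci[0]:.1f} to {r.delta_E_ci[1]:.1f})")
    print(f"  ICER = {r.icer.ratio:.1f} EUR/day ({r.icer.tag})")
    q = r.quadrants
    print(f"  CE plane: NE {q['NE']:.1f}% SE {q['SE']:.1f}% "
          f"SW {q['SW']:.1f}% NW {q['NW']:.1f}%")
    ceac50 = r.ceac.loc[r.ceac['wtp'] == 50.0, 'p_cost_effective'].iloc[0]
    print(f"  P(cost-effective) at WTP EUR 50/day: {ceac50:.2f}")

print()
for r in roi_analysis(cohort, B=2000, seed=5):
    print(f"{r.comparison}: NB = EUR {r.net_benefit:+.0f} "
          f"({r.ci['net_benefit'][0]:.0f} to {r.ci['net_benefit'][1]:.0f}), "
          f"BCR = {r.bcr:.1f}, ROI = {r.roi:.0f}%, "
          f"P(positive return) = {r.prob_positive_return:.2f}")

print("\nA 'dominant' ICER means cheaper AND more effective (southeast "
      "quadrant); NB > 0 means the intervention's societal savings exceed "
      "its delivery cost.")
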