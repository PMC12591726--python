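# trialecon

Trial-based effectiveness and health-economic evaluation for three-arm
randomized trials of vocational return-to-work (RTW) interventions, modelled
on the MI-NAV trial setting: workers on long-term sickness absence due to
musculoskeletal disorders, randomized to usual case management (UC), UC plus
motivational interviewing (MI), or UC plus a stratified vocational advice
intervention (SVAI), followed for 12 months.

Registry data of this kind are confidential, so the package ships a
**synthetic cohort generator** whose parameters are the trial contrasts
themselves (absence-day shifts, monthly RTW hazard ratios, benefit-receipt
odds ratios, intervention unit costs). Every downstream stage is therefore
testable by parameter recovery, with no data download.

## What it computes

**Effectiveness** (`trialecon.effectiveness`)

* Sickness-absence days: Mann–Whitney U and robust (Huber, k = 1.345) linear
  regression, unadjusted and adjusted for the preplanned covariate set.
* Time to sustained RTW — the first four consecutive months with < 50 %
  absence from contracted hours: Kaplan–Meier (Greenwood variance, log–log
  CIs), log-rank, and a Cox proportional-hazards model with all three arms in
  one model (Efron ties; Breslow behind a flag).
* Monthly wage-replacement-benefit receipt: pooled person-month logit with
  month fixed effects and participant-clustered variance (GEE option).
* Repeated MSK-HQ scores: linear mixed model with random intercepts and a
  group × time interaction (marginal GEE-unstructured option).

**Economic evaluation** (`trialecon.costing`, `trialecon.econ`)

* Societal costing: micro-costed intervention costs, human-capital valuation
  of absenteeism (days × gender-stratified daily wage), unpaid-productivity
  losses, QALYs from EQ-5D-5L utilities.
* Multiple imputation by chained equations with predictive mean matching and
  Rubin's rules: T = W + (1 + 1/M)·B.
* Seemingly unrelated regressions of costs and effects, a stratified
  nonparametric bootstrap of the incremental pairs (ΔC, ΔE), the ICER ΔC/ΔE
  with dominance classification, CE-plane quadrant shares, cost-effectiveness
  acceptability curves P(λ·ΔE − ΔC > 0), and the ROI metrics
  NB = benefits − costs, BCR = benefits/costs, ROI = (benefits − costs)/costs × 100.

## Worked example

```python
from trialecon import ce_analysis, generate_cohort, roi_analysis, trial_calibrated_config

cohort = generate_cohort(trial_calibrated_config(seed=5))   # 509 participants
for r in ce_analysis(cohort, effect="days", B=2000, seed=5):
    print(r.comparison, round(r.delta_C), round(r.delta_E, 1),
          r.icer.tag, round(r.quadrants["SE"], 1))
```

Running `python examples/05_cost_effectiveness.py` (which adds the ROI
analysis) prints:

```
UC+MI vs UC:
  delta C = EUR -191 (-1430 to 955)
  delta E = +21.0 days averted (4.5 to 37.6)
  ICER = -9.1 EUR/day (dominant)
  CE plane: NE 37.6% SE 61.7% SW 0.6% NW 0.1%
  P(cost-effective) at WTP EUR 50/day: 0.96
...
UC+MI vs UC: NB = EUR +5110 (1331 to 8981), BCR = 87.9, ROI = 8694%, P(positive return) = 1.00
UC+SVAI vs UC: NB = EUR +5471 (1512 to 9272), BCR = 69.2, ROI = 6825%, P(positive return) = 1.00
```

ΔC is the incremental non-absenteeism societal cost, ΔE the sickness-absence
days averted versus UC; "dominant" means cheaper *and* more effective. NB is
the per-worker societal saving net of the intervention's delivery cost, and
P(positive return) the bootstrap probability that the payer's investment pays
for itself. Numbers vary with the seed: this is one synthetic cohort at the
trial's sample size.

The other scripts in `examples/` walk through simulation, the six
effectiveness analyses, imputation, costing, and the full pipeline. The same
pipeline is scriptable from a shell:

```bash
trialecon all --out run/ --seed 6 --bootstrap 2000 --imputations 5
cat run/report.txt     # Table 2-5 analogues for the current run
```

## Layout

```
src/trialecon/
  config.py         arm specs, cohort config, YAML I/O, calibrated defaults
  cohort.py         cohort container, CSV round trip, invariant checks
  generator.py      synthetic trial generator + MAR missingness overlay
  effectiveness.py  the six outcome analyses
  imputation.py     MICE-PMM and Rubin's rules
  costing.py        micro-costing, valuation, QALYs, cost table
  econ.py           SUR, bootstrap, ICER/CEAC/quadrants, ROI
  pipeline.py       staged pipeline with persisted intermediates + manifest
  cli.py            `trialecon simulate|impute|analyze|evaluate|report|all`
```

See `docs/methods.md` for the statistical model, generator assumptions,
default parameters, and known limitations.
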