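# Methods

## Setting and estimands

The package implements the 12-month effectiveness and societal-perspective
economic evaluation of a three-arm randomized trial of vocational
return-to-work (RTW) support for workers on long-term sickness absence:
usual case management (UC) versus UC + motivational interviewing (MI) versus
UC + stratified vocational advice (SVAI). The estimands are

* the difference in registry sickness-absence days over 12 months (arm − UC),
* the hazard ratio for *sustained RTW* — the first four-week period at
  50–100 % of contracted hours without relapse,
* the monthly odds ratio of receiving wage-replacement benefits,
* the difference in repeated MSK-HQ scores (0–56) at each follow-up,
* incremental societal costs and effects (ΔC, ΔE), the ICER, the CEAC, and
  the return-on-investment metrics NB, BCR and ROI.

## Synthetic cohort generator

Real registry linkage is confidential, so all inputs are emulated by a
generator whose parameters *are* the arm contrasts; the analyses are then
validated by parameter recovery.

**Monthly work-status trajectory.** Each participant enters fully or
partially absent: a configurable share (default 0.60) is 100 % absent, the
rest uniform on 50–90 % of contracted hours. From month 2 onward, sustained
RTW occurs with a constant monthly hazard (UC default 0.083); arm hazard
ratios act on the complementary-log-log scale,
h_arm = 1 − (1 − h_UC)^HR, so the discrete-time model is proportional-hazards
on the grouped-time scale the Cox model sees. Mild covariate heterogeneity
(workability, age) enters the individual log-hazard with coefficients ±0.10.
After RTW, transient one-month relapses occur with probability 0.05/month.
The UC hazard was chosen to reproduce the roughly 55 % probability of no
sustained RTW at month 8 and a mean of ~7.5 absent months, which, with the
default wages, yields a UC absenteeism cost mean near €35 600/year.

**Registry absence days** are the panel-implied days (absence fraction ×
21.67 working days/month) plus a small Gaussian registry-vs-panel
discrepancy (SD 3 days) plus the arm's additive `absence_day_shift`, clipped
at zero. The shift perturbs only the recorded days — it stands in for
day-level differences a monthly panel cannot resolve — so the panel and the
day count remain separately coherent. The total between-arm day difference
is the hazard-induced difference plus the shift; the trial-calibrated config
sets both so the realized differences land near −15.6 (MI) and −17.6 (SVAI)
days.

**Benefit receipt.** With `benefit_odds_ratio = 1` (the default), receipt is
coupled to the panel: a benefit is received in any month with positive
absence ("any day" definition; a "full month" definition is available).
With any other value, receipt is drawn from a logistic model
P(benefit | month m) = expit(logit(p_m^UC) + ln OR), where p_m^UC is the
analytic UC any-absence prevalence. This makes the configured OR the exact
estimand of the pooled person-month logit, which a coupled mechanism cannot
guarantee (the RTW hazard itself moves monthly prevalence — in fact a hazard
ratio of 1.27 alone implies a pooled OR near 0.74). The cost is that months
become conditionally independent within person in that regime, so the
cluster-robust variance is conservative there.

**Costs.** Healthcare components and unpaid-productivity hours are
zero-inflated gammas (primary care: 10 % zeros, shape 1, mean €1046;
secondary: 40 % zeros, shape 0.6, mean €141; unpaid hours: 55 % zeros,
shape 0.5, mean 186 h at €15/h), scaled per arm. Intervention costs are
truncated normal around the arm's unit cost (SD €40). Absenteeism cost is
*deterministically* absence days × gender-stratified daily wage (defaults
€240 male / €210 female — configurable placeholders from
official-statistics-style average incomes, not any trial's confidential
rates). This construction reproduces the > 90 % absenteeism share of
societal costs by design. Utilities are truncated normal on [−0.594, 1]
(baseline mean 0.55; 12-month mean 0.68 plus arm shifts), correlated 0.4
with baseline.

**Missingness** is missing-at-random by construction: the probability that a
cell is absent depends only on arm, age and sex through a logistic score
whose intercept is solved (Brent) so the marginal rate equals the configured
per-variable rate. Defaults emulate near-complete baseline covariates
(0.2–4 % missing) and questionnaire attrition at follow-up (27–42 % for
MSK-HQ, 15 % for utilities and unpaid-productivity costs). A total cost with
any missing component is itself missing.

**Seeding.** One master seed; each stage (covariates, trajectory, costs,
scores, missingness) derives its generator from a fixed offset of that seed,
so identical config + seed gives byte-identical output tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: day-level absence spells (monthly resolution
cannot reproduce the trial's *median* of 85 absence days simultaneously
with its 8-month median time to sustained RTW; the generator prioritizes the
survival curve and cost means, giving a higher median), informative
(non-MAR) dropout, within-person correlation of benefit receipt in the
odds-adjusted regime, seasonal effects, and recruitment/stratified
randomization mechanics (arm labels are assigned directly).

## Statistical choices

* **"Robust regression"** is Huber M-estimation with tuning constant 1.345;
  OLS with HC3 errors is available as a sensitivity flag. The estimator for
  grouped-median-like contrasts is not uniquely determined by common usage,
  so both are exposed.
* **Sustained RTW with monthly granularity**: the four-week qualifying
  period becomes month m plus the three following months all below the 50 %
  absence threshold; `window=1` gives the single-qualifying-month
  alternative. Events are only detectable through month 9 of a 12-month
  panel; later returns are censored at 12.
* **Cox ties**: Efron by default (monthly times are heavily tied); Breslow
  behind a flag. Months with universal benefit receipt are dropped from the
  benefit logit — their month intercept is infinite and they carry no
  information about the arm contrast.
* **Mixed model**: random intercepts with independent residuals by default.
  A random-intercept model and an unstructured covariance are mutually
  inconsistent specifications, so the unstructured variant is provided as a
  marginal GEE with unstructured working correlation rather than asserted as
  the "right" reading.
* **Adjustment set** (all adjusted analyses, single three-arm models): age,
  sex, education, prior-year absence days, workability, baseline MSK-HQ,
  physical activity, employer follow-up.
* No multiplicity adjustment across the two pairwise contrasts.

## Imputation

Chained equations with classic type-0 predictive mean matching: each
incomplete variable is regressed by OLS on all other analysis variables plus
arm indicators; a missing cell receives the observed value of one of the
`donors` (default 5) candidates with nearest predicted means. Ten cycles,
M = 10 completed datasets by default. Binary variables are imputed via PMM
on a linear score, which keeps them in the observed support. Cost variables
are imputed at component level and totals recomputed, preserving the
accounting identity. Between-imputation variability comes from the random
initial fills and donor draws; without a Bayesian parameter draw this
slightly understates between-imputation variance, which matters little at
the trial's missingness rates and is the price of an exactly testable donor
contract. Both covariates and outcomes are imputed by default (restrict via
`variables=`). Pooling uses Rubin's rules with Barnard–Rubin degrees of
freedom when a complete-data df is supplied.

## Economic evaluation

Costs and effects are estimated jointly by a two-equation SUR (first-stage
OLS residuals estimate the 2 × 2 error covariance; feasible GLS solves the
stacked system — with identical regressors this equals per-equation OLS
exactly, which is also how it is tested). Uncertainty comes from a
nonparametric bootstrap of participants, resampled with replacement within
arm to preserve arm sizes. With an imputation stack, the B replicates are
split evenly across the M completed datasets and the clouds pooled
(impute-then-bootstrap); the alternative nesting is not implemented as a
default because it multiplies runtime by M without changing the tested
estimands.

For the sickness-absence outcome, absenteeism cost is excluded from the cost
side *by construction in the estimator wiring* — the days averted are the
monetized outcome, and keeping their wage value on both sides would double
count. For the QALY outcome the full societal total is used. QALYs default
to the single-point construction (12-month utility × 1 year); a linear-AUC
trapezoid over available timepoints is available (`auc-linear`) because a
single-point annual QALY is methodologically unusual.

ICER tags: "dominant" (ΔC ≤ 0 < ΔE), "dominated" (ΔE < 0 ≤ ΔC),
"tradeoff" otherwise, "undefined" at ΔE = 0 (no ratio). CE-plane quadrants
classify the sign of (ΔE, ΔC) with exact zeros assigned to the
effective/cheaper side (probability ~0 with continuous data). The CEAC is
p(λ) = P(λ·ΔE − ΔC > 0) on a non-negative strictly increasing λ grid
(defaults 0–€100 000 by €1000 for QALYs; 0–€500 by €10 for absence days).
Cost-benefit wiring: costs are the incremental intervention costs; benefits
the reduction in all other societal costs, so NB = −ΔC_total and
ROI ≡ (BCR − 1) × 100 identically.

## Problem sizes used in the test suite

Parameter-recovery checks run at n = 5000/arm (tolerances: ±2 days for the
absence-day shift, ±10 % relative for hazard and odds ratios). The
end-to-end sign/ordering reproduction of the cost, cost-effectiveness and
ROI tables runs at n = 2000/arm with B = 2000, M = 5: the smallest tested
contrast (the net-benefit gap between the two intervention arms, ~€2000,
with a per-arm total-cost SD near €28 000) needs the standard error of a
difference of differences below ~€900, i.e. about 1900 participants per
arm. The acceptance script's synthetic replication uses the trial's own
sample size (171/169/169), where such orderings are *not* expected to be
stable — it reports magnitudes, not hypothesis tests.

## Known limitations

* No discounting (12-month horizon) and no friction-cost valuation
  (human-capital only), matching the evaluated design.
* The generator's monthly resolution overstates the median absence-day count
  relative to day-level registries (see above).
* `prepare_ce_inputs` requires complete cost/effect data and deliberately
  refuses to silently drop rows; run the imputation module first.
* The pooled Table-3 analogue in the pipeline approximates per-imputation
  variances from bootstrap CI half-widths before Rubin pooling.
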