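"""Synthetic three-arm RTW trial cohorts.

The monthly work-status trajectory follows a discrete-time hazard model: each
participant starts absent for a baseline fraction of contracted hours (full
absence for a configurable share, partial 50-90% otherwise) and, from month 2
on, experiences sustained return to work (RTW) with a constant monthly hazard.
Arm hazard ratios act on the complementary-log-log scale. After RTW, transient
one-month relapses occur at a configurable rate.

Registry absence days are the panel-implied days (absence fraction x working
days per month) plus the arm's additive ``absence_day_shift``; absenteeism cost
is always absence days x the gender-stratified daily wage (exact identity,
shared with :mod:`trialecon.costing`).

Wage-replacement-benefit receipt is coupled to any absence in the month when
an arm's ``benefit_odds_ratio`` is 1; otherwise it is drawn from a logistic
model with month-specific intercepts taken from the UC reference prevalence
curve, so the configured odds ratio is the estimand of the pooled
person-month logit model (see docs/methods.md for the rationale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .cohort import Cohort, COST_COMPONENTS
from .config import ArmSpec, CohortConfig, ConfigurationError
from .costing import value_absenteeism_array, value_unpaid_productivity

_MSKHQ_GAIN = {0: 0.0, 3: 5.5, 6: 7.5, 9: 8.0, 12: 8.0}
_UTILITY_FLOOR = -0.594
_SHADOW_PRICE_DEFAULT = 15.0

# fixed per-stage offsets under the master seed (single master seed contract)
_STAGE = {"covariates": 11, "trajectory": 12, "costs": 13, "scores": 14,
          "missingness": 15}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], seed])


def _arm_hazard(base: float, hazard_ratio: float) -> float:
    # proportional hazards on the complementary-log-log scale
    return 1.0 - (1.0 - base) ** hazard_ratio


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete (no missing values) cohort under ``config``.

    Deterministic given ``config.seed``; identical config + seed yields
    byte-identical tables.
    """
    config.validate()
    months = config.months
    seed = config.seed
    rng_cov = _rng(seed, "covariates")
    rng_traj = _rng(seed, "trajectory")
    rng_cost = _rng(seed, "costs")
    rng_score = _rng(seed, "scores")

    base_rows = []
    panel_rows = []
    pid_counter = 0
    for arm_idx, arm in enumerate(config.arms):
        n = arm.n
        ids = np.array([f"P{pid_counter + i:05d}" for i in range(n)])
        pid_counter += n

        # --- baseline covariates ------------------------------------------
        age = np.clip(rng_cov.normal(48.0, 10.0, n), 18, 67)
        sex = np.where(rng_cov.random(n) < config.female_proportion,
                       "female", "male")
        education = np.where(rng_cov.random(n) < 0.37, "high", "low")
        workability = np.clip(np.round(rng_cov.normal(3.0, 2.6, n)), 0, 10)
        phys = np.where(rng_cov.random(n) < 0.60, "low", "high")
        prior_days = np.clip(np.exp(rng_cov.normal(np.log(36.0), 0.7, n)), 1, 200)
        base_days = np.clip(np.exp(rng_cov.normal(np.log(51.0), 0.8, n)), 0, 300)
        employer = (rng_cov.random(n) < 0.70).astype(float)
        risk = np.where(rng_cov.random(n) < config.risk_group_proportion,
                        "high", "medium/low")

        # --- monthly trajectory -------------------------------------------
        full = rng_traj.random(n) < config.full_absence_proportion
        frac0 = np.where(full, 1.0, rng_traj.uniform(0.5, 0.9, n))

        h_arm = _arm_hazard(config.base_rtw_hazard, arm.rtw_hazard_ratio)
        # mild covariate heterogeneity in the individual hazard (cloglog scale)
        lin = 0.10 * (workability - 3.0) / 2.6 - 0.10 * (age - 48.0) / 10.0
        h_i = 1.0 - (1.0 - h_arm) ** np.exp(lin)
        # sustained-RTW transition month; earliest month 2 (all enter absent)
        draws = rng_traj.random((n, months))
        transition = np.full(n, months + 1)
        for m in range(2, months + 1):
            hit = (transition > months) & (draws[:, m - 1] < h_i)
            transition[hit] = m
        relapse = rng_traj.random((n, months)) < config.relapse_rate

        month_idx = np.arange(1, months + 1)
        returned = month_idx[None, :] >= transition[:, None]
        frac = np.where(returned & ~relapse, 0.0, frac0[:, None])
        frac = np.where(returned & relapse, frac0[:, None], frac)
        frac = np.where(~returned, frac0[:, None], frac)

        # --- benefit receipt ----------------------------------------------
        if arm.benefit_odds_ratio == 1.0:
            if config.benefit_definition == "any_day":
                benefit = (frac > 0).astype(int)
            else:  # full_month
                benefit = (frac >= 1.0).astype(int)
        else:
            p_ref = _uc_reference_prevalence(config, month_idx)
            q = expit(logit(np.clip(p_ref, 1e-9, 1 - 1e-9))
                      + np.log(arm.benefit_odds_ratio))
            benefit = (rng_traj.random((n, months)) < q[None, :]).astype(int)

        # --- registry absence days and costs ------------------------------
        panel_days = frac.sum(axis=1) * config.working_days_per_month
        noise = rng_cost.normal(0.0, 3.0, n)  # registry/panel discrepancy
        absence_days = np.clip(panel_days + arm.absence_day_shift + noise, 0, None)
        cost_absent = value_absenteeism_array(absence_days, sex, config.wage_table)

        cd = config.cost_distributions
        cost_primary = _zero_inflated_gamma(
            rng_cost, cd["healthcare_primary"], arm.healthcare_cost_scale, n)
        cost_secondary = _zero_inflated_gamma(
            rng_cost, cd["healthcare_secondary"], arm.healthcare_cost_scale, n)
        unpaid_hours = _zero_inflated_gamma(
            rng_cost, cd["unpaid_hours"], arm.unpaid_productivity_scale, n)
        cost_unpaid = np.array([
            value_unpaid_productivity(h, _SHADOW_PRICE_DEFAULT) for h in unpaid_hours
        ])
        if arm.intervention_unit_cost > 0:
            sd = cd.get("intervention_sd", 0.0)
            cost_interv = np.clip(
                rng_cost.normal(arm.intervention_unit_cost, sd, n), 0, None)
        else:
            cost_interv = np.zeros(n)
        cost_total = (cost_interv + cost_primary + cost_secondary
                      + cost_absent + cost_unpaid)

        # --- repeated MSK-HQ and utilities --------------------------------
        msk0 = np.clip(np.round(rng_score.normal(27.0, 8.5, n)), 0, 56)
        b_i = rng_score.normal(0.0, 5.0, n)
        msk = {0: msk0}
        for t in (3, 6, 9, 12):
            ramp = arm.mskhq_shift_12m * t / 12.0
            score = (msk0 + _MSKHQ_GAIN[t] + ramp + b_i
                     + rng_score.normal(0.0, 5.0, n))
            msk[t] = np.clip(np.round(score), 0, 56)

        um = config.utility_model
        u0 = _truncated_normal(rng_score, um["baseline_mean"], um["baseline_sd"],
                               _UTILITY_FLOOR, 1.0, n)
        shift = um.get("arm_shifts", {}).get(arm.label, 0.0)
        u12 = (um["followup_mean"] + shift
               + 0.4 * (u0 - um["baseline_mean"])
               + rng_score.normal(0.0, 0.9 * um["followup_sd"], n))
        u12 = np.clip(u12, _UTILITY_FLOOR, 1.0)

        base_rows.append(pd.DataFrame({
            "id": ids, "arm": arm.label, "age": np.round(age, 1), "sex": sex,
            "education": education, "workability": workability,
            "physical_activity": phys,
            "prior_absence_days": np.round(prior_days, 1),
            "baseline_absence_days": np.round(base_days, 1),
            "employer_followup": employer, "risk_group": risk,
            "mskhq_0": msk[0], "mskhq_3": msk[3], "mskhq_6": msk[6],
            "mskhq_9": msk[9], "mskhq_12": msk[12],
            "utility_baseline": u0, "utility_12m": u12,
            "absence_days": absence_days, "unpaid_hours": unpaid_hours,
            "cost_intervention": cost_interv,
            "cost_healthcare_primary": cost_primary,
            "cost_healthcare_secondary": cost_secondary,
            "cost_absenteeism": cost_absent, "cost_unpaid": cost_unpaid,
            "cost_total": cost_total,
        }))
        panel_rows.append(pd.DataFrame({
            "id": np.repeat(ids, months),
            "month": np.tile(month_idx, n),
            "absence_fraction": frac.reshape(-1),
            "benefit_received": benefit.reshape(-1),
        }))

    baseline = pd.concat(base_rows, ignore_index=True)
    panel = pd.concat(panel_rows, ignore_index=True)
    return Cohort(baseline, panel, months=months,
                  meta={"seed": seed, "arms": [a.label for a in config.arms]})


def _zero_inflated_gamma(rng, params: dict, scale_mult: float, n: int) -> np.ndarray:
    """Zero-inflated gamma draws with unconditional mean params['mean']*scale."""
    zero_mass, shape, mean = params["zero_mass"], params["shape"], params["mean"]
    mean = mean * scale_mult
    if mean == 0:
        return np.zeros(n)
    scale = mean / ((1.0 - zero_mass) * shape)
    vals = rng.gamma(shape, scale, n)
    vals[rng.random(n) < zero_mass] = 0.0
    return vals


def _uc_reference_prevalence(config: CohortConfig, month_idx: np.ndarray) -> np.ndarray:
    """Analytic UC-arm probability of any absence (benefit receipt) per month."""
    h = config.base_rtw_hazard
    # transition earliest at month 2: P(not yet returned by month m)
    s = np.where(month_idx <= 1, 1.0, (1.0 - h) ** (month_idx - 1))
    return s + (1.0 - s) * config.relapse_rate


# ---------------------------------------------------------------------------
# MAR missingness overlay
# ---------------------------------------------------------------------------

_MISSABLE = {
    "workability", "physical_activity", "employer_followup",
    "mskhq_0", "mskhq_3", "mskhq_6", "mskhq_9", "mskhq_12",
    "utility_baseline", "utility_12m",
    "cost_healthcare_primary", "cost_healthcare_secondary",
    "cost_unpaid", "unpaid_hours",
}


def impose_missingness(cohort: Cohort, config: CohortConfig) -> Cohort:
    """Overlay missing-at-random absence of values on a complete cohort.

    The probability that a cell is missing depends only on fully observed
    covariates (arm, age, sex); the per-variable intercept is solved so the
    marginal missingness rate equals the configured rate.
    """
    out = cohort.copy()
    b = out.baseline
    if len(b) == 0:
        return out
    rng = _rng(config.seed, "missingness")
    arm_codes = pd.Categorical(b["arm"]).codes
    score = (0.02 * (b["age"].to_numpy() - b["age"].mean())
             + 0.30 * (b["sex"].to_numpy() == "female")
             + 0.10 * arm_codes)
    score = score - score.mean()

    for var, rate in config.missingness_rates.items():
        col = "mskhq_0" if var == "mskhq" else var
        if rate >= 1:
            raise ConfigurationError(f"missingness rate for {var!r} must be < 1")
        if rate <= 0:
            continue
        if col not in _MISSABLE:
            raise ConfigurationError(f"cannot impose missingness on {var!r}")

        def marginal(c):
            return expit(c + score).mean() - rate

        c0 = brentq(marginal, -30, 30)
        p = expit(c0 + score)
        mask = rng.random(len(b)) < p
        if col in ("cost_unpaid", "unpaid_hours"):
            # the iPCQ instrument yields both; they go missing together
            b.loc[mask, "cost_unpaid"] = np.nan
            b.loc[mask, "unpaid_hours"] = np.nan
        else:
            b.loc[mask, col] = np.nan

    # a total with an absent component is itself unknown
    b["cost_total"] = b[COST_COMPONENTS].sum(axis=1, skipna=False)
    return out
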