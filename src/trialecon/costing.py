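"""Societal-perspective costing: micro-costed intervention costs, wage-valued
absenteeism (human-capital approach), unpaid-work productivity losses,
currency conversion, QALY construction, and the arm-level cost table.

All valuations are linear in their inputs, and a participant's total cost is
exactly the sum of the five components — both properties are relied on by the
economic evaluation (component differences add up to the total difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ADJUSTMENT_COVARIATES, Cohort, COST_COMPONENTS


@dataclass
class CostProfile:
    """One participant's 12-month societal costs by component (EUR)."""

    intervention: float
    healthcare_primary: float
    healthcare_secondary: float
    absenteeism: float
    unpaid_productivity: float

    def __post_init__(self):
        for name in ("intervention", "healthcare_primary", "healthcare_secondary",
                     "absenteeism", "unpaid_productivity"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost component {name} must be >= 0")

    @property
    def total(self) -> float:
        return (self.intervention + self.healthcare_primary
                + self.healthcare_secondary + self.absenteeism
                + self.unpaid_productivity)


@dataclass
class MicroCostingInputs:
    """Bottom-up intervention costing: resource units times unit prices."""

    training_hours: float = 0.0
    training_rate: float = 0.0       # EUR per training hour
    mentoring_hours: float = 0.0
    mentoring_rate: float = 0.0
    session_minutes: float = 0.0     # delivery time per session
    sessions_per_participant: float = 0.0
    delivery_rate: float = 0.0       # EUR per delivery hour
    overhead_fraction: float = 0.0

    def __post_init__(self):
        for f in ("training_hours", "training_rate", "mentoring_hours",
                  "mentoring_rate", "session_minutes",
                  "sessions_per_participant", "delivery_rate",
                  "overhead_fraction"):
            if getattr(self, f) < 0:
                raise ValueError(f"MicroCostingInputs.{f} must be >= 0")


@dataclass
class QALYValue:
    qaly: float
    construction: str  # "single-point" | "auc-linear"


def micro_cost_intervention(inputs: MicroCostingInputs, n_participants: int) -> float:
    """Intervention cost per participant (EUR).

    Training and mentoring are programme-level costs amortized over all
    participants; delivery time is per participant; overhead multiplies the
    whole.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    programme = (inputs.training_hours * inputs.training_rate
                 + inputs.mentoring_hours * inputs.mentoring_rate)
    delivery = (inputs.session_minutes / 60.0 * inputs.sessions_per_participant
                * inputs.delivery_rate)
    return (programme / n_participants + delivery) * (1.0 + inputs.overhead_fraction)


def value_absenteeism(absence_days: float, sex: str, wage_table: dict) -> float:
    """Absence days valued at the gender-stratified average daily wage."""
    if sex not in wage_table:
        raise KeyError(f"no wage table entry for sex {sex!r}")
    if absence_days < 0:
        raise ValueError("absence_days must be >= 0")
    return absence_days * wage_table[sex]


def value_absenteeism_array(absence_days, sex, wage_table: dict) -> np.ndarray:
    """Vectorized :func:`value_absenteeism` (same identity, arraywise)."""
    sex = np.asarray(sex)
    for s in np.unique(sex):
        if s not in wage_table:
            raise KeyError(f"no wage table entry for sex {s!r}")
    wages = np.array([wage_table[s] for s in sex], dtype=float)
    return np.asarray(absence_days, dtype=float) * wages


def value_unpaid_productivity(hours_lost: float, shadow_price: float) -> float:
    """Unpaid-work hours lost valued at a shadow price (EUR/hour)."""
    if hours_lost < 0 or shadow_price < 0:
        raise ValueError("hours_lost and shadow_price must be >= 0")
    return hours_lost * shadow_price


def convert_currency(amount: float, index_factor: float = 1.0,
                     exchange_rate: float = 1.0) -> float:
    """Price-index and exchange-rate conversion (pure scaling)."""
    if exchange_rate <= 0:
        raise ValueError("exchange_rate must be > 0")
    return amount * index_factor * exchange_rate


def compute_qaly(utilities: dict, construction: str = "single-point") -> QALYValue:
    """QALYs over 12 months from EQ-5D-5L utility scores.

    ``utilities`` maps month (0..12) to utility. ``single-point`` takes the
    12-month utility times one year; ``auc-linear`` integrates the trapezoid
    over the available timepoints (in years).
    """
    pts = {m: u for m, u in utilities.items() if u is not None and not np.isnan(u)}
    if not pts:
        raise ValueError("no utility values supplied")
    if construction == "single-point":
        if 12 not in pts:
            raise ValueError("single-point construction requires the 12-month utility")
        return QALYValue(pts[12] * 1.0, "single-point")
    if construction == "auc-linear":
        months = sorted(pts)
        if len(months) == 1:
            return QALYValue(pts[months[0]] * 1.0, "auc-linear")
        auc = 0.0
        for a, b in zip(months[:-1], months[1:]):
            auc += (pts[a] + pts[b]) / 2.0 * (b - a) / 12.0
        auc *= 12.0 / (months[-1] - months[0])  # rescale span to one year
        return QALYValue(auc, "auc-linear")
    raise ValueError(f"unknown QALY construction {construction!r}")


# ---------------------------------------------------------------------------
# Arm-level cost table (means, SEMs, differences with bootstrap CIs)
# ---------------------------------------------------------------------------

_COMPONENT_LABELS = {
    "cost_intervention": "Intervention costs",
    "cost_healthcare_primary": "Healthcare costs, primary",
    "cost_healthcare_secondary": "Healthcare costs, secondary",
    "cost_absenteeism": "Absenteeism costs",
    "cost_unpaid": "Productivity losses of unpaid work",
    "cost_total": "Total societal costs",
}


def cost_difference_table(cohort_or_baseline, reference: str = "UC",
                          adjusted: bool = False, n_boot: int = 1000,
                          seed: int = 0) -> pd.DataFrame:
    """Per-component arm means and differences versus the reference arm.

    Differences come from a linear model on arm indicators (plus the standard
    adjustment covariates when ``adjusted``); confidence intervals are
    bias-corrected bootstrap percentile intervals, resampling participants
    within arm.

    Requires complete cost data; run the imputation module first if the
    cohort has missing components.
    """
    b = (cohort_or_baseline.baseline if isinstance(cohort_or_baseline, Cohort)
         else cohort_or_baseline)
    cols = COST_COMPONENTS + ["cost_total"]
    if b[cols].isna().any().any():
        raise ValueError(
            "cost components contain missing values; impute first "
            "(trialecon.imputation.mice_pmm) or drop incomplete rows"
        )
    all_arms = list(pd.unique(b["arm"]))
    arms = [a for a in all_arms if a != reference]
    rng = np.random.default_rng(seed)

    design = _design(b, reference, adjusted)
    X_full = design.to_numpy(dtype=float)
    Y_full = b[cols].to_numpy(dtype=float)
    arm_rows = {a: design.columns.get_loc(f"arm_{a}") for a in arms}
    strata = [np.flatnonzero((b["arm"] == a).to_numpy()) for a in all_arms]

    def _diffs(idx: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X_full[idx], Y_full[idx], rcond=None)
        return beta  # rows: design columns, cols: components

    all_idx = np.arange(len(b))
    point = _diffs(all_idx)
    boots = np.empty((n_boot, X_full.shape[1], len(cols)))
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                              for s in strata])
        boots[i] = _diffs(idx)

    rows = []
    groups = {a: b[b["arm"] == a] for a in all_arms}
    for j, comp in enumerate(cols):
        row = {"component": _COMPONENT_LABELS[comp], "column": comp}
        for arm, g in groups.items():
            row[f"mean_{arm}"] = g[comp].mean()
            row[f"sem_{arm}"] = g[comp].std(ddof=1) / np.sqrt(len(g))
        for arm in arms:
            est = point[arm_rows[arm], j]
            lcl, ucl = _bc_interval(boots[:, arm_rows[arm], j], est)
            row[f"diff_{arm}"] = est
            row[f"lcl_{arm}"] = lcl
            row[f"ucl_{arm}"] = ucl
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["adjusted"] = adjusted
    return out


def _design(frame: pd.DataFrame, reference: str, adjusted: bool) -> pd.DataFrame:
    X = pd.get_dummies(frame["arm"], prefix="arm", dtype=float)
    ref_col = f"arm_{reference}"
    if ref_col not in X:
        raise ValueError(f"reference arm {reference!r} not present")
    X = X.drop(columns=ref_col)
    if adjusted:
        for cov in ADJUSTMENT_COVARIATES:
            v = frame[cov]
            if v.dtype.kind in "fiu":
                X[cov] = v.astype(float).fillna(v.astype(float).mean())
            else:
                X[cov] = (v == v.mode().iloc[0]).astype(float)
    X.insert(0, "const", 1.0)
    return X


def _bc_interval(draws: np.ndarray, estimate: float,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected (BC, no acceleration) bootstrap percentile interval."""
    from scipy.stats import norm
    prop = np.mean(draws < estimate)
    prop = min(max(prop, 1.0 / (len(draws) + 1)), 1 - 1.0 / (len(draws) + 1))
    z0 = norm.ppf(prop)
    lo = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    hi = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    return (float(np.quantile(draws, lo)), float(np.quantile(draws, hi)))
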