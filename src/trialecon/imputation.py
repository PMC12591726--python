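"""Multiple imputation by chained equations with predictive mean matching
(PMM), and Rubin's-rules pooling.

Each incomplete variable is regressed (ordinary least squares) on every other
analysis variable plus the arm indicators; a missing cell is replaced by the
observed value of one of the ``donors`` candidates whose predicted means are
nearest the cell's predicted mean (classic type-0 PMM: imputed values always
belong to the observed support, so binary variables stay binary). The chained
cycle runs ``iterations`` times per completed dataset; between-imputation
variability comes from the random initial fills and donor draws.

Cost variables are imputed at component level and totals recomputed, so the
accounting identity total = sum(components) survives imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ADJUSTMENT_COVARIATES, Cohort, COST_COMPONENTS

_BINARY_MAPS = {
    "sex": {"male": 0.0, "female": 1.0},
    "education": {"low": 0.0, "high": 1.0},
    "physical_activity": {"low": 0.0, "high": 1.0},
    "risk_group": {"medium/low": 0.0, "high": 1.0},
}

# numeric analysis variables usable as predictors / imputation targets
_NUMERIC_VARS = [
    "age", "workability", "prior_absence_days", "baseline_absence_days",
    "employer_followup", "mskhq_0", "mskhq_3", "mskhq_6", "mskhq_9",
    "mskhq_12", "utility_baseline", "utility_12m", "absence_days",
    "unpaid_hours",
] + COST_COMPONENTS


@dataclass
class ImputationStack:
    """M completed baseline tables plus the metadata needed to reproduce them."""

    datasets: list[pd.DataFrame]
    variables: list[str]
    iterations: int
    donors: int
    seed: int
    chain_means: pd.DataFrame | None = None  # trace of imputed-cell means
    models: dict = field(default_factory=dict)  # variable -> last OLS coefs

    @property
    def M(self) -> int:
        return len(self.datasets)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m, df in enumerate(self.datasets):
            df.to_csv(directory / f"imputed_{m:02d}.csv", index=False)
        manifest = {"M": self.M, "seed": self.seed, "iterations": self.iterations,
                    "donors": self.donors, "variables": self.variables}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, directory) -> "ImputationStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        datasets = [pd.read_csv(directory / f"imputed_{m:02d}.csv",
                                dtype={"id": str, "arm": str, "sex": str})
                    for m in range(manifest["M"])]
        return cls(datasets, manifest["variables"], manifest["iterations"],
                   manifest["donors"], manifest["seed"])


@dataclass
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    lcl: float
    ucl: float


def _encode(baseline: pd.DataFrame) -> pd.DataFrame:
    z = pd.DataFrame(index=baseline.index)
    for col, mapping in _BINARY_MAPS.items():
        z[col] = baseline[col].map(mapping)
    for col in _NUMERIC_VARS:
        z[col] = baseline[col].astype(float)
    for arm in sorted(pd.unique(baseline["arm"]))[1:]:
        z[f"arm_{arm}"] = (baseline["arm"] == arm).astype(float)
    return z


def _decode(z: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    out = template.copy()
    for col, mapping in _BINARY_MAPS.items():
        inv = {v: k for k, v in mapping.items()}
        out[col] = z[col].round().map(inv)
    for col in _NUMERIC_VARS:
        out[col] = z[col]
    out["cost_total"] = out[COST_COMPONENTS].sum(axis=1)
    return out


def mice_pmm(cohort_or_baseline, variables: list[str] | None = None,
             M: int = 10, iterations: int = 10, donors: int = 5,
             seed: int = 0) -> ImputationStack:
    """Multiply impute missing values by chained equations with PMM.

    Parameters
    ----------
    cohort_or_baseline : Cohort or baseline DataFrame.
    variables : columns to impute; default all encoded variables with any
        missing value (covariates and outcomes alike; restrict to impute
        outcomes only).
    M, iterations, donors : completed datasets, chained cycles per dataset,
        and PMM donor-pool size.
    """
    baseline = (cohort_or_baseline.baseline
                if isinstance(cohort_or_baseline, Cohort) else cohort_or_baseline)
    if M < 2:
        raise ValueError("M must be >= 2")
    z0 = _encode(baseline)
    if variables is None:
        variables = [c for c in z0.columns
                     if not c.startswith("arm_") and z0[c].isna().any()]
    else:
        variables = list(variables)
    for v in variables:
        if v not in z0.columns:
            raise ValueError(f"unknown imputation variable {v!r}")
        n_obs = int(z0[v].notna().sum())
        if n_obs == 0:
            raise ValueError(f"variable {v!r} is fully absent; cannot impute")
        if donors > n_obs:
            raise ValueError(
                f"donors={donors} exceeds {n_obs} observed values of {v!r}")

    masks = {v: z0[v].isna().to_numpy() for v in variables}
    datasets, trace_rows, models = [], [], {}
    for m in range(M):
        rng = np.random.default_rng([int(seed) % (2**31), 97, m])
        z = z0.copy()
        for v in variables:  # random initial fill from the observed support
            obs = z0.loc[~masks[v], v].to_numpy()
            z.loc[masks[v], v] = rng.choice(obs, size=int(masks[v].sum()),
                                            replace=True)
        for it in range(iterations):
            for v in variables:
                if not masks[v].any():
                    continue
                coef = _pmm_step(z, v, masks[v], donors, rng)
                models[v] = coef
                trace_rows.append({"dataset": m, "iteration": it, "variable": v,
                                   "imputed_mean": z.loc[masks[v], v].mean()})
        datasets.append(_decode(z, baseline))

    trace = pd.DataFrame(trace_rows) if trace_rows else None
    return ImputationStack(datasets, variables, iterations, donors, int(seed),
                           chain_means=trace, models=models)


def _pmm_step(z: pd.DataFrame, var: str, mask: np.ndarray, donors: int,
              rng: np.random.Generator) -> np.ndarray:
    """One chained-equation update of ``var``; returns the OLS coefficients."""
    predictors = [c for c in z.columns if c != var]
    X = z[predictors].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    y = z[var].to_numpy(dtype=float)
    obs = ~mask
    coef, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    pred = X @ coef
    pred_obs = pred[obs]
    y_obs_true = z[var].to_numpy()[obs]  # observed values (never changed)
    mis_idx = np.flatnonzero(mask)
    col = z.columns.get_loc(var)
    imputed = np.empty(len(mis_idx))
    # chunked donor search keeps the |obs| x |mis| distance matrix small
    for start in range(0, len(mis_idx), 1024):
        chunk = mis_idx[start:start + 1024]
        dist = np.abs(pred_obs[None, :] - pred[chunk][:, None])
        pool = np.argpartition(dist, donors - 1, axis=1)[:, :donors]
        pick = rng.integers(0, donors, size=len(chunk))
        imputed[start:start + 1024] = y_obs_true[pool[np.arange(len(chunk)), pick]]
    z.iloc[mis_idx, col] = imputed
    return coef


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_pool(estimates, variances, df_complete: float | None = None,
               alpha: float = 0.05) -> PooledEstimate:
    """Pool per-dataset estimates and variances by Rubin's rules.

    Total variance T = W + (1 + 1/M) B; degrees of freedom follow
    Barnard–Rubin when ``df_complete`` is given, the classical large-sample
    formula otherwise.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    M = len(q)
    if M < 2:
        raise ValueError("pooling requires M >= 2")
    qbar = q.mean()
    W = u.mean()
    B = q.var(ddof=1)
    T = W + (1 + 1 / M) * B
    if B == 0 or T == 0:
        df = np.inf
    else:
        r = (1 + 1 / M) * B / W if W > 0 else np.inf
        df_old = (M - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else M - 1
        if df_complete is None:
            df = df_old
        else:
            lam = (1 + 1 / M) * B / T
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1 / (1 / df_old + 1 / df_obs)
    from scipy.stats import t as tdist
    crit = tdist.ppf(1 - alpha / 2, df) if np.isfinite(df) else \
        tdist.ppf(1 - alpha / 2, 1e12)
    half = crit * np.sqrt(T)
    return PooledEstimate(float(qbar), float(W), float(B), float(T), float(df),
                          float(qbar - half), float(qbar + half))
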