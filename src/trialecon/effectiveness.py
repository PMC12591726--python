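"""Twelve-month effectiveness analyses on a three-arm cohort.

Six analyses, each with an unadjusted and a covariate-adjusted variant where
the design calls for one:

* sickness absence days — Mann–Whitney U and robust (Huber) linear regression;
* time to sustained RTW — Kaplan–Meier, log-rank, Cox proportional hazards;
* monthly wage-replacement-benefit receipt — pooled person-month logit with
  month fixed effects and cluster-robust variance;
* repeated MSK-HQ scores — linear mixed model with random intercepts
  (group x time interaction, baseline score as covariate).

All multi-group analyses fit a single model containing all three arms with
UC as the reference, never pairwise refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .cohort import ADJUSTMENT_COVARIATES, Cohort


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalOutcome:
    """Months until sustained RTW (event) or censoring at end of follow-up."""

    time: int
    event: int

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.time < 1:
            raise ValueError("time must be >= 1")


@dataclass
class EffectEstimate:
    comparison: str
    estimate: float
    lcl: float
    ucl: float
    scale: str          # difference-in-days | hazard-ratio | odds-ratio | score-points
    adjusted: bool
    p_value: float | None = None

    def __post_init__(self):
        if not (self.lcl <= self.estimate <= self.ucl):
            raise ValueError(
                f"{self.comparison}: CI ({self.lcl}, {self.ucl}) does not bracket "
                f"estimate {self.estimate}"
            )
        if self.scale in ("hazard-ratio", "odds-ratio") and self.estimate <= 0:
            raise ValueError(f"{self.comparison}: ratio-scale estimate must be > 0")


# ---------------------------------------------------------------------------
# Sustained RTW detection
# ---------------------------------------------------------------------------

def sustained_rtw_detector(absence_fractions, threshold: float = 0.5,
                           window: int = 4, months: int = 12) -> SurvivalOutcome:
    """Detect the month of sustained RTW in a monthly absence panel.

    Sustained RTW at month ``m`` means the absence fraction is below
    ``threshold`` in month ``m`` and the ``window - 1`` following months (a
    four-week qualifying period extended to four consecutive months, the
    finest sustained window a monthly registry panel can resolve; set
    ``window=1`` for the single-qualifying-month alternative). Participants
    with no qualifying month are censored at ``months``.
    """
    frac = np.asarray(absence_fractions, dtype=float)
    if len(frac) < months:
        raise ValueError(f"panel has {len(frac)} months, expected >= {months}")
    frac = frac[:months]
    qualifies = frac < threshold
    for m in range(1, months - window + 2):
        if qualifies[m - 1: m - 1 + window].all():
            return SurvivalOutcome(time=m, event=1)
    return SurvivalOutcome(time=months, event=0)


def survival_outcomes(cohort: Cohort, threshold: float = 0.5,
                      window: int = 4) -> pd.DataFrame:
    """Per-participant sustained-RTW outcomes (id, arm, time, event)."""
    months = cohort.months
    wide = (cohort.panel.pivot(index="id", columns="month",
                               values="absence_fraction")
            .reindex(cohort.baseline["id"]))
    frac = wide.to_numpy(dtype=float)
    qualifies = frac[:, :months] < threshold
    # sliding AND over `window` consecutive months
    ok = qualifies[:, : months - window + 1].copy()
    for w in range(1, window):
        ok &= qualifies[:, w: months - window + 1 + w]
    any_event = ok.any(axis=1)
    first = np.where(any_event, ok.argmax(axis=1) + 1, months)
    return pd.DataFrame({
        "id": cohort.baseline["id"].to_numpy(),
        "arm": cohort.baseline["arm"].to_numpy(),
        "time": first.astype(int),
        "event": any_event.astype(int),
    })


# ---------------------------------------------------------------------------
# Absence days
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U statistic (of ``x``) and two-sided p-value.

    Exact enumeration when both samples have at most eight untied values,
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _arm_design(b: pd.DataFrame, reference: str, adjusted: bool) -> pd.DataFrame:
    X = pd.get_dummies(b["arm"], prefix="arm", dtype=float)
    ref = f"arm_{reference}"
    if ref not in X.columns:
        raise ValueError(f"reference arm {reference!r} not in data")
    X = X.drop(columns=ref)
    if adjusted:
        for cov in ADJUSTMENT_COVARIATES:
            v = b[cov]
            if v.dtype.kind in "fiu":
                X[cov] = v.astype(float)
            else:
                X[cov] = (v == sorted(v.dropna().unique())[0]).astype(float)
    X.insert(0, "const", 1.0)
    return X


def _check_collinearity(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < A.shape[1]:
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"collinear design columns: {bad}")


def robust_linear_diff(cohort_or_df, outcome: str = "absence_days",
                       reference: str = "UC", adjusted: bool = False,
                       estimator: str = "huber") -> list[EffectEstimate]:
    """Arm differences in an outcome from one robust linear model.

    ``estimator='huber'`` is Huber M-estimation (tuning constant 1.345);
    ``estimator='ols'`` is ordinary least squares with HC3 robust standard
    errors, for sensitivity.
    """
    b = cohort_or_df.baseline if isinstance(cohort_or_df, Cohort) else cohort_or_df
    cols = [outcome, "arm"] + (ADJUSTMENT_COVARIATES if adjusted else [])
    b = b.dropna(subset=[c for c in cols if c in b.columns])
    arms = [a for a in pd.unique(b["arm"]) if a != reference]
    X = _arm_design(b, reference, adjusted)
    y = b[outcome].to_numpy(dtype=float)

    if np.var(y) == 0:
        warnings.warn("outcome has zero variance; coefficients degenerate at 0",
                      RuntimeWarning, stacklevel=2)
        return [EffectEstimate(f"{a} vs {reference}", 0.0, 0.0, 0.0,
                               "difference-in-days", adjusted, None)
                for a in arms]

    _check_collinearity(X)
    if estimator == "huber":
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(1.345)).fit()
    elif estimator == "ols":
        fit = sm.OLS(y, X).fit(cov_type="HC3")
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    z = scipy.stats.norm.ppf(0.975)
    out = []
    for a in arms:
        name = f"arm_{a}"
        est, se = fit.params[name], fit.bse[name]
        p = 2 * scipy.stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        out.append(EffectEstimate(f"{a} vs {reference}", est,
                                  est - z * se, est + z * se,
                                  "difference-in-days", adjusted, p))
    return out


# ---------------------------------------------------------------------------
# Time to sustained RTW
# ---------------------------------------------------------------------------

def kaplan_meier(outcomes: pd.DataFrame, months: int = 12) -> pd.DataFrame:
    """Product-limit estimate of P(no sustained RTW) per month with 95% CI
    (Greenwood variance, log-log transformed intervals)."""
    if len(outcomes) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(outcomes["time"], outcomes["event"])
    grid = np.arange(1, months + 1)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_
    # step function: carry the value at the largest event time <= each month
    lcl = _step_at(ci.iloc[:, 0], grid)
    ucl = _step_at(ci.iloc[:, 1], grid)
    return pd.DataFrame({"month": grid, "survival": surv,
                         "lcl": lcl, "ucl": ucl})


def _step_at(series: pd.Series, grid: np.ndarray) -> np.ndarray:
    idx = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    out = np.empty(len(grid))
    for i, t in enumerate(grid):
        mask = idx <= t
        out[i] = vals[mask][-1] if mask.any() else vals[0]
    return out


def log_rank(outcomes: pd.DataFrame, group_col: str = "arm") -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across the groups."""
    counts = outcomes.groupby(group_col).size()
    if len(counts) < 2:
        raise ValueError("log-rank test requires >= 2 groups")
    if (counts == 0).any():
        raise ValueError("log-rank test: empty group")
    res = multivariate_logrank_test(outcomes["time"], outcomes[group_col],
                                    outcomes["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(outcomes: pd.DataFrame, baseline: pd.DataFrame | None = None,
           reference: str = "UC", adjusted: bool = False,
           ties: str = "efron") -> list[EffectEstimate]:
    """Hazard ratios for sustained RTW from one Cox model with all arms.

    Efron tie handling by default (monthly event times are heavily tied);
    ``ties='breslow'`` for the coarser approximation.
    """
    df = outcomes
    if adjusted:
        if baseline is None:
            raise ValueError("adjusted Cox model needs the baseline table")
        df = df.merge(baseline[["id"] + ADJUSTMENT_COVARIATES], on="id")
        df = df.dropna(subset=ADJUSTMENT_COVARIATES)
    X = _arm_design(df, reference, adjusted).drop(columns="const")
    _check_collinearity(X)
    model = PHReg(df["time"].to_numpy(dtype=float), X.to_numpy(dtype=float),
                  status=df["event"].to_numpy(), ties=ties)
    fit = model.fit()
    score = model.score(fit.params)
    gnorm = float(np.linalg.norm(score))
    if not np.all(np.isfinite(fit.params)) or gnorm > 1e-2 * len(df):
        raise ConvergenceError(
            f"Cox partial likelihood did not converge (gradient norm {gnorm:.3g})")
    z = scipy.stats.norm.ppf(0.975)
    arms = [a for a in pd.unique(df["arm"]) if a != reference]
    out = []
    for a in arms:
        j = list(X.columns).index(f"arm_{a}")
        coef, se = fit.params[j], fit.bse[j]
        p = 2 * scipy.stats.norm.sf(abs(coef / se))
        out.append(EffectEstimate(f"{a} vs {reference}", float(np.exp(coef)),
                                  float(np.exp(coef - z * se)),
                                  float(np.exp(coef + z * se)),
                                  "hazard-ratio", adjusted, p))
    return out


# ---------------------------------------------------------------------------
# Monthly wage-replacement benefits
# ---------------------------------------------------------------------------

def monthly_benefit_model(cohort: Cohort, reference: str = "UC",
                          adjusted: bool = False,
                          method: str = "cluster") -> list[EffectEstimate]:
    """Odds ratios for monthly benefit receipt from a pooled person-month
    logit with month fixed effects.

    ``method='cluster'`` uses GLM with variance clustered on participant;
    ``method='gee'`` fits a GEE with exchangeable working correlation.
    """
    long = cohort.panel.merge(cohort.baseline[["id", "arm"]
                                              + ADJUSTMENT_COVARIATES],
                              on="id")
    if adjusted:
        long = long.dropna(subset=ADJUSTMENT_COVARIATES)
    if long["benefit_received"].nunique() < 2:
        raise ValueError("benefit outcome is constant (all zero or all one)")
    # months where receipt is universal (or absent) carry no information on
    # the arm contrast but make their month intercept infinite; drop them
    per_month = long.groupby("month")["benefit_received"].nunique()
    keep = per_month[per_month > 1].index
    long = long[long["month"].isin(keep)]
    y = long["benefit_received"].to_numpy(dtype=float)
    X = _arm_design(long, reference, adjusted)
    if long["month"].nunique() > 1:
        mdum = pd.get_dummies(long["month"], prefix="month", dtype=float)
        X = pd.concat([X, mdum.iloc[:, 1:]], axis=1)
    _check_collinearity(X)
    groups = pd.Categorical(long["id"]).codes
    if method == "cluster":
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": groups})
    elif method == "gee":
        fit = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(),
                     cov_struct=sm.cov_struct.Exchangeable()).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    z = scipy.stats.norm.ppf(0.975)
    out = []
    for a in [a for a in pd.unique(long["arm"]) if a != reference]:
        name = f"arm_{a}"
        coef, se = fit.params[name], fit.bse[name]
        p = 2 * scipy.stats.norm.sf(abs(coef / se))
        out.append(EffectEstimate(f"{a} vs {reference}", float(np.exp(coef)),
                                  float(np.exp(coef - z * se)),
                                  float(np.exp(coef + z * se)),
                                  "odds-ratio", adjusted, p))
    return out


# ---------------------------------------------------------------------------
# MSK-HQ mixed model
# ---------------------------------------------------------------------------

def mskhq_long(cohort: Cohort) -> pd.DataFrame:
    """Follow-up MSK-HQ scores in long format with the baseline score."""
    b = cohort.baseline
    frames = []
    for t in (3, 6, 9, 12):
        col = f"mskhq_{t}"
        sub = b[["id", "arm", "mskhq_0", col]].rename(columns={col: "score"})
        sub["time"] = t
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    return long.dropna(subset=["score"])


def mskhq_mixed_model(cohort_or_long, reference: str = "UC",
                      covariance: str = "random_intercept",
                      include_baseline: bool = True) -> list[EffectEstimate]:
    """Arm-versus-UC differences in MSK-HQ at each follow-up from a repeated
    measures model with a group x time interaction.

    ``covariance='random_intercept'`` fits a linear mixed model with a random
    intercept per participant and independent residuals;
    ``covariance='unstructured'`` fits the marginal model by GEE with an
    unstructured working correlation over the four follow-ups.
    """
    long = (mskhq_long(cohort_or_long) if isinstance(cohort_or_long, Cohort)
            else cohort_or_long.dropna(subset=["score"]))
    if len(long) == 0:
        raise ValueError("no post-baseline MSK-HQ scores")
    if include_baseline:
        long = long.dropna(subset=["mskhq_0"])
    times = sorted(long["time"].unique())
    arms = [a for a in pd.unique(long["arm"]) if a != reference]

    X = pd.DataFrame({"const": np.ones(len(long))}, index=long.index)
    for a in arms:
        X[f"arm_{a}"] = (long["arm"] == a).astype(float)
    for t in times[1:]:
        X[f"time_{t}"] = (long["time"] == t).astype(float)
    for a in arms:
        for t in times[1:]:
            X[f"arm_{a}:time_{t}"] = X[f"arm_{a}"] * X[f"time_{t}"]
    if include_baseline:
        X["mskhq_0"] = long["mskhq_0"].to_numpy(dtype=float)
    _check_collinearity(X)

    y = long["score"].to_numpy(dtype=float)
    groups = pd.Categorical(long["id"]).codes
    if covariance == "random_intercept":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        k = len(X.columns)
        params = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:k, :k]
    elif covariance == "unstructured":
        tcodes = long["time"].map({t: i for i, t in enumerate(times)}).to_numpy()
        fit = sm.GEE(y, X, groups=groups, time=tcodes,
                     family=sm.families.Gaussian(),
                     cov_struct=sm.cov_struct.Unstructured()).fit()
        params, cov = fit.params, fit.cov_params()
    else:
        raise ValueError(f"unknown covariance {covariance!r}")

    names = list(X.columns)
    z = scipy.stats.norm.ppf(0.975)
    out = []
    for a in arms:
        for t in times:
            L = np.zeros(len(names))
            L[names.index(f"arm_{a}")] = 1.0
            if t != times[0]:
                L[names.index(f"arm_{a}:time_{t}")] = 1.0
            est = float(L @ np.asarray(params))
            se = float(np.sqrt(L @ np.asarray(cov) @ L))
            p = 2 * scipy.stats.norm.sf(abs(est / se)) if se > 0 else np.nan
            out.append(EffectEstimate(f"{a} vs {reference} @ {t}m", est,
                                      est - z * se, est + z * se,
                                      "score-points", True, p))
    return out
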