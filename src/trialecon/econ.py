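"""Economic evaluation core: seemingly unrelated regressions (SUR) of costs
and effects, nonparametric bootstrap of the incremental pairs, ICERs with
dominance classification, cost-effectiveness plane quadrants, acceptability
curves, and cost-benefit / return-on-investment metrics.

Conventions
-----------
* Effects are oriented so larger is better: QALYs gained, or sickness-absence
  days *averted* relative to usual care.
* When the effect is absence days, absenteeism cost is excluded from the cost
  side by construction — the days are the monetized outcome and keeping their
  wage value on both sides would double count.
* The bootstrap resamples participants with replacement within arm
  (stratified), preserving arm sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ADJUSTMENT_COVARIATES, Cohort
from .imputation import ImputationStack

QUADRANTS = ("NE", "SE", "SW", "NW")


# ---------------------------------------------------------------------------
# SUR
# ---------------------------------------------------------------------------

@dataclass
class SURResult:
    params: list[np.ndarray]          # per-equation coefficient vectors
    names: list[list[str]]            # per-equation regressor names
    cov: np.ndarray                   # joint coefficient covariance
    sigma: np.ndarray                 # 2x2 cross-equation residual covariance
    delta_C: dict[str, float]
    delta_E: dict[str, float]

    def param_cov(self, eq_i: int, name_i: str, eq_j: int, name_j: str) -> float:
        oi = sum(len(n) for n in self.names[:eq_i]) + self.names[eq_i].index(name_i)
        oj = sum(len(n) for n in self.names[:eq_j]) + self.names[eq_j].index(name_j)
        return float(self.cov[oi, oj])


def sur_system(ys: list[np.ndarray], Xs: list[pd.DataFrame]):
    """Feasible-GLS estimate of a system of regressions with correlated errors.

    First-stage OLS residuals estimate the cross-equation error covariance
    Sigma; the second stage solves the stacked GLS system with weight
    Sigma^-1 (x) I. With identical regressor matrices this reduces exactly to
    per-equation least squares.
    """
    k = len(ys)
    n = len(ys[0])
    for y, X in zip(ys, Xs):
        if len(y) != n or len(X) != n:
            raise ValueError("all equations must share the same observations")
    Xmats = [np.asarray(X, dtype=float) for X in Xs]
    betas, resids = [], []
    for y, X in zip(ys, Xmats):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix in SUR equation")
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        betas.append(b)
        resids.append(y - X @ b)
    R = np.column_stack(resids)
    sigma = (R.T @ R) / n
    sigma_inv = np.linalg.inv(sigma)

    ps = [X.shape[1] for X in Xmats]
    ptot = sum(ps)
    A = np.zeros((ptot, ptot))
    bvec = np.zeros(ptot)
    offs = np.concatenate([[0], np.cumsum(ps)])
    for i in range(k):
        for j in range(k):
            blk = sigma_inv[i, j] * (Xmats[i].T @ Xmats[j])
            A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = blk
        bvec[offs[i]:offs[i + 1]] = sum(
            sigma_inv[i, j] * (Xmats[i].T @ ys[j]) for j in range(k))
    beta = np.linalg.solve(A, bvec)
    cov = np.linalg.inv(A)
    split = [beta[offs[i]:offs[i + 1]] for i in range(k)]
    return split, cov, sigma


def _ce_design(df: pd.DataFrame, reference: str, adjusted: bool) -> pd.DataFrame:
    X = pd.get_dummies(df["arm"], prefix="arm", dtype=float)
    ref = f"arm_{reference}"
    if ref not in X.columns:
        raise ValueError(f"reference arm {reference!r} not in data")
    X = X.drop(columns=ref)
    if adjusted:
        for cov in ADJUSTMENT_COVARIATES:
            v = df[cov]
            if v.dtype.kind in "fiu":
                X[cov] = v.astype(float)
            else:
                X[cov] = (v == sorted(v.dropna().unique())[0]).astype(float)
    X.insert(0, "const", 1.0)
    return X


def sur_fit(df: pd.DataFrame, reference: str = "UC",
            adjusted: bool = False) -> SURResult:
    """Two-equation SUR of cost and effect on arm indicators (+ covariates).

    ``df`` needs columns ``cost``, ``effect``, ``arm`` (and the adjustment
    covariates when ``adjusted``). The arm coefficients are the incremental
    cost (delta_C) and incremental effect (delta_E) versus the reference.
    """
    X = _ce_design(df, reference, adjusted)
    ys = [df["cost"].to_numpy(dtype=float), df["effect"].to_numpy(dtype=float)]
    (bc, be), cov, sigma = sur_system(ys, [X, X])
    names = list(X.columns)
    arms = [c[4:] for c in names if c.startswith("arm_")]
    dC = {a: float(bc[names.index(f"arm_{a}")]) for a in arms}
    dE = {a: float(be[names.index(f"arm_{a}")]) for a in arms}
    return SURResult([bc, be], [names, names], cov, sigma, dC, dE)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ce(data, B: int = 10_000, seed: int = 0, estimator=None,
                 reference: str = "UC", adjusted: bool = False) -> pd.DataFrame:
    """Bootstrap cloud of (delta_C, delta_E) pairs per comparison.

    ``data`` is a prepared cost/effect DataFrame (see :func:`prepare_ce_inputs`)
    or a list of M such frames from an imputation stack, in which case B is
    split evenly across the completed datasets and the clouds pooled.
    Resampling is with replacement, stratified by arm. Deterministic given
    ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if estimator is None:
        def estimator(frame):
            res = sur_fit(frame, reference=reference, adjusted=adjusted)
            return res.delta_C, res.delta_E

    frames = data if isinstance(data, list) else [data]
    reps = _split_reps(B, len(frames))
    rows = []
    for d, (frame, b_d) in enumerate(zip(frames, reps)):
        rng = np.random.default_rng([seed % (2**31), 211, d])
        strata = [np.flatnonzero((frame["arm"] == a).to_numpy())
                  for a in pd.unique(frame["arm"])]
        for r in range(b_d):
            for _attempt in range(100):
                idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                                      for s in strata])
                sub = frame.iloc[idx]
                try:
                    dC, dE = estimator(sub)
                    break
                except (ValueError, np.linalg.LinAlgError):
                    continue  # pathological resample: redraw
            else:
                raise RuntimeError("bootstrap replicate failed repeatedly")
            for a in dC:
                rows.append((a, d, r, dC[a], dE[a]))
    return pd.DataFrame(rows, columns=["comparison", "dataset", "replicate",
                                       "delta_C", "delta_E"])


def _split_reps(B: int, m: int) -> list[int]:
    base = B // m
    extra = B - base * m
    return [base + (1 if i < extra else 0) for i in range(m)]


# ---------------------------------------------------------------------------
# ICER, CE plane, CEAC
# ---------------------------------------------------------------------------

@dataclass
class ICERValue:
    ratio: float | None
    tag: str  # dominant | dominated | tradeoff | undefined


def icer(delta_C: float, delta_E: float) -> ICERValue:
    """Incremental cost-effectiveness ratio with dominance classification."""
    if delta_E == 0:
        return ICERValue(None, "undefined")
    ratio = delta_C / delta_E
    if delta_C <= 0 < delta_E:
        tag = "dominant"
    elif delta_E < 0 <= delta_C:
        tag = "dominated"
    else:
        tag = "tradeoff"
    return ICERValue(float(ratio), tag)


def ce_plane_distribution(cloud: pd.DataFrame) -> dict[str, float]:
    """Quadrant percentages of the bootstrap cloud.

    Quadrants by sign of (delta_E, delta_C): NE=(+,+), SE=(+,-), SW=(-,-),
    NW=(-,+). Exact zeros are assigned to the effective/cheaper side
    (delta_E = 0 counts as +E, delta_C = 0 counts as -C), so a pair at the
    origin lands in SE.
    """
    if len(cloud) == 0:
        raise ValueError("empty bootstrap cloud")
    dE = cloud["delta_E"].to_numpy(dtype=float)
    dC = cloud["delta_C"].to_numpy(dtype=float)
    e_pos = dE >= 0
    c_pos = dC > 0
    counts = {
        "NE": np.sum(e_pos & c_pos), "SE": np.sum(e_pos & ~c_pos),
        "SW": np.sum(~e_pos & ~c_pos), "NW": np.sum(~e_pos & c_pos),
    }
    n = len(cloud)
    return {q: 100.0 * counts[q] / n for q in QUADRANTS}


@dataclass
class WTPGrid:
    """Willingness-to-pay grid (EUR per effect unit), non-negative, increasing."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) == 0 or (v < 0).any() or (np.diff(v) <= 0).any():
            raise ValueError("WTP grid must be non-negative and strictly increasing")
        self.values = v

    @classmethod
    def for_qaly(cls, ceiling: float = 100_000.0, step: float = 1000.0):
        return cls(np.arange(0.0, ceiling + step / 2, step))

    @classmethod
    def for_absence_days(cls, ceiling: float = 500.0, step: float = 10.0):
        return cls(np.arange(0.0, ceiling + step / 2, step))


def ceac(cloud: pd.DataFrame, grid: WTPGrid) -> pd.DataFrame:
    """Probability of positive net monetary benefit lambda*dE - dC per lambda."""
    if len(cloud) == 0:
        raise ValueError("empty bootstrap cloud")
    dE = cloud["delta_E"].to_numpy(dtype=float)
    dC = cloud["delta_C"].to_numpy(dtype=float)
    probs = [(lam * dE - dC > 0).mean() for lam in grid.values]
    return pd.DataFrame({"wtp": grid.values, "p_cost_effective": probs})


# ---------------------------------------------------------------------------
# Cost-benefit / ROI
# ---------------------------------------------------------------------------

@dataclass
class ROIResult:
    costs: float
    benefits: float
    net_benefit: float
    bcr: float | None
    roi: float | None
    prob_positive_return: float | None = None
    ci: dict = field(default_factory=dict)
    comparison: str = ""


def cba_metrics(benefits: float, costs: float) -> ROIResult:
    """Net benefit, benefit-cost ratio and return on investment.

    NB = benefits - costs; BCR = benefits / costs; ROI = (benefits - costs) /
    costs x 100. With zero costs NB is still defined but the ratio metrics
    are tagged undefined (None).
    """
    nb = benefits - costs
    if costs > 0:
        bcr = benefits / costs
        roi = (benefits - costs) / costs * 100.0
    elif costs == 0:
        bcr = roi = None
    else:
        raise ValueError("costs must be >= 0")
    return ROIResult(costs, benefits, nb, bcr, roi)


def prob_positive_return(nb_draws) -> float:
    """Fraction of bootstrap net-benefit draws that are positive."""
    draws = np.asarray(nb_draws, dtype=float)
    if len(draws) < 100:
        raise ValueError("need >= 100 bootstrap draws")
    return float((draws > 0).mean())


# ---------------------------------------------------------------------------
# Wiring: cohort -> CE inputs -> full analysis
# ---------------------------------------------------------------------------

@dataclass
class CEResult:
    comparison: str
    effect_unit: str
    delta_C: float
    delta_C_ci: tuple[float, float]
    delta_E: float
    delta_E_ci: tuple[float, float]
    icer: ICERValue
    cloud: pd.DataFrame
    quadrants: dict[str, float]
    ceac: pd.DataFrame


def prepare_ce_inputs(baseline: pd.DataFrame, effect: str = "days") -> pd.DataFrame:
    """Build the cost/effect frame for the CE estimator.

    ``effect='days'``: effect is negative absence days (so the arm contrast is
    days averted) and cost excludes absenteeism (double-counting rule,
    enforced here by construction). ``effect='qaly'``: effect is the
    single-point QALY and cost is the full societal total.
    """
    df = baseline.copy()
    if effect == "days":
        df["effect"] = -df["absence_days"].astype(float)
        df["cost"] = (df["cost_total"] - df["cost_absenteeism"]).astype(float)
    elif effect == "qaly":
        df["effect"] = df["utility_12m"].astype(float)  # x 1 year
        df["cost"] = df["cost_total"].astype(float)
    else:
        raise ValueError(f"unknown effect {effect!r}")
    cols = ["arm", "cost", "effect"] + [c for c in ADJUSTMENT_COVARIATES
                                        if c in df.columns]
    out = df[cols]
    if out[["cost", "effect"]].isna().any().any():
        raise ValueError("cost/effect inputs contain missing values; impute first")
    return out


def ce_analysis(data, effect: str = "days", B: int = 10_000, seed: int = 0,
                reference: str = "UC", adjusted: bool = False,
                grid: WTPGrid | None = None) -> list[CEResult]:
    """Full cost-effectiveness (or cost-utility) analysis.

    ``data`` is a Cohort / baseline DataFrame with complete cost data, or an
    :class:`~trialecon.imputation.ImputationStack` (bootstrap runs within each
    completed dataset and the clouds are pooled).
    """
    if isinstance(data, ImputationStack):
        frames = [prepare_ce_inputs(d, effect) for d in data.datasets]
        point_frames = frames
    else:
        baseline = data.baseline if isinstance(data, Cohort) else data
        frames = prepare_ce_inputs(baseline, effect)
        point_frames = [frames]
    if grid is None:
        grid = WTPGrid.for_absence_days() if effect == "days" else WTPGrid.for_qaly()

    # point estimate: SUR per dataset, averaged over the stack
    dCs, dEs = [], []
    for f in point_frames:
        res = sur_fit(f, reference=reference, adjusted=adjusted)
        dCs.append(res.delta_C)
        dEs.append(res.delta_E)
    arms = list(dCs[0])
    point_C = {a: float(np.mean([d[a] for d in dCs])) for a in arms}
    point_E = {a: float(np.mean([d[a] for d in dEs])) for a in arms}

    cloud = bootstrap_ce(frames, B=B, seed=seed, reference=reference,
                         adjusted=adjusted)
    out = []
    for a in arms:
        sub = cloud[cloud["comparison"] == a].reset_index(drop=True)
        ci_C = tuple(np.quantile(sub["delta_C"], [0.025, 0.975]))
        ci_E = tuple(np.quantile(sub["delta_E"], [0.025, 0.975]))
        out.append(CEResult(
            comparison=f"{a} vs {reference}",
            effect_unit="days averted" if effect == "days" else "QALY",
            delta_C=point_C[a], delta_C_ci=ci_C,
            delta_E=point_E[a], delta_E_ci=ci_E,
            icer=icer(point_C[a], point_E[a]),
            cloud=sub, quadrants=ce_plane_distribution(sub),
            ceac=ceac(sub, grid),
        ))
    return out


def roi_analysis(data, B: int = 10_000, seed: int = 0,
                 reference: str = "UC") -> list[ROIResult]:
    """Cost-benefit analysis: intervention costs versus monetized savings.

    Costs are the incremental intervention costs; benefits are the reduction
    in all other societal costs (absenteeism, healthcare, unpaid productivity)
    versus the reference arm, so NB = -(incremental total societal cost).
    Percentile CIs and the probability of positive return come from the same
    stratified bootstrap as the CE analysis.
    """
    if isinstance(data, ImputationStack):
        frames = data.datasets
    else:
        baseline = data.baseline if isinstance(data, Cohort) else data
        frames = [baseline]

    def _roi_frame(b: pd.DataFrame) -> pd.DataFrame:
        df = b.copy()
        df["cost"] = df["cost_intervention"].astype(float)
        df["effect"] = (df["cost_total"] - df["cost_intervention"]).astype(float)
        return df[["arm", "cost", "effect"]]

    prepared = [_roi_frame(b) for b in frames]

    def estimator(frame):
        res = sur_fit(frame, reference=reference, adjusted=False)
        costs = res.delta_C                      # incremental intervention cost
        benefits = {a: -v for a, v in res.delta_E.items()}  # savings elsewhere
        return costs, benefits

    point_c, point_b = {}, {}
    for f in prepared:
        c, bnf = estimator(f)
        for a in c:
            point_c.setdefault(a, []).append(c[a])
            point_b.setdefault(a, []).append(bnf[a])

    cloud = bootstrap_ce(prepared, B=B, seed=seed, estimator=estimator)
    out = []
    for a in point_c:
        costs = float(np.mean(point_c[a]))
        benefits = float(np.mean(point_b[a]))
        res = cba_metrics(benefits, costs)
        sub = cloud[cloud["comparison"] == a]
        b_draws = sub["delta_E"].to_numpy(dtype=float)
        c_draws = sub["delta_C"].to_numpy(dtype=float)
        nb_draws = b_draws - c_draws
        with np.errstate(divide="ignore", invalid="ignore"):
            bcr_draws = np.where(c_draws > 0, b_draws / c_draws, np.nan)
        res.prob_positive_return = prob_positive_return(nb_draws)
        res.ci = {
            "costs": tuple(np.quantile(c_draws, [0.025, 0.975])),
            "benefits": tuple(np.quantile(b_draws, [0.025, 0.975])),
            "net_benefit": tuple(np.quantile(nb_draws, [0.025, 0.975])),
            "bcr": tuple(np.nanquantile(bcr_draws, [0.025, 0.975])),
        }
        res.comparison = f"{a} vs {reference}"
        out.append(res)
    return out
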