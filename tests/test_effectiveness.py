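"""Effectiveness analyses against brute-force oracles and hand-worked examples."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats
from hypothesis import given, settings, strategies as st

from trialecon import (Cohort, SurvivalOutcome, cox_ph, kaplan_meier, log_rank,
                       mann_whitney_u, monthly_benefit_model, mskhq_mixed_model,
                       robust_linear_diff, survival_outcomes,
                       sustained_rtw_detector)
from conftest import toy_survival


# ---------------------------------------------------------------------------
# Sustained-RTW detector
# ---------------------------------------------------------------------------

def brute_force_rtw(frac, threshold=0.5, window=4, months=12):
    """Oracle: scan every possible window exhaustively."""
    for m in range(1, months + 1):
        if m + window - 1 > months:
            break
        if all(frac[k] < threshold for k in range(m - 1, m - 1 + window)):
            return m, 1
    return months, 0


@pytest.mark.parametrize("frac, expected", [
    ([1.0] * 12, (12, 0)),                                  # never returns
    ([1.0] * 5 + [0.0] * 7, (6, 1)),                        # clean return at 6
    ([1.0, 1.0, 1.0, 0.3, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], (7, 1)),
    ([0.0] * 12, (1, 1)),                                   # immediate
    ([1.0] * 9 + [0.0] * 3, (12, 0)),                       # too late to sustain
])
def test_detector_examples(frac, expected):
    so = sustained_rtw_detector(frac)
    assert (so.time, so.event) == expected
    assert brute_force_rtw(frac) == expected


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.sampled_from([0.0, 0.3, 0.6, 1.0]), min_size=12, max_size=12))
def test_detector_matches_brute_force(frac):
    so = sustained_rtw_detector(frac)
    assert (so.time, so.event) == brute_force_rtw(frac)


def test_detector_short_panel_rejected():
    with pytest.raises(ValueError, match="panel"):
        sustained_rtw_detector([1.0] * 5)


def test_detector_single_month_window():
    so = sustained_rtw_detector([1.0, 0.2, 1.0, 1.0] + [1.0] * 8, window=1)
    assert (so.time, so.event) == (2, 1)


def test_survival_outcomes_match_rowwise_detector(small_cohort):
    so = survival_outcomes(small_cohort)
    for _, row in so.sample(25, random_state=1).iterrows():
        frac = small_cohort.panel_for(row["id"])["absence_fraction"].to_numpy()
        t, e = brute_force_rtw(frac)
        assert (row["time"], row["event"]) == (t, e)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mann_whitney_identities():
    x = np.arange(10.0)
    u, _ = mann_whitney_u(x + 0.5, x + 0.25)  # near-identical, no ties
    assert abs(u - 50.0) <= 10
    u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0


def test_mann_whitney_pair_counting_oracle():
    x, y = [1, 3, 5], [2, 4, 6]
    u, _ = mann_whitney_u(x, y)
    oracle = sum(xi > yj for xi in x for yj in y)
    assert u == oracle == 3


def test_mann_whitney_exact_vs_normal_p():
    """Exact and tie-corrected normal p agree within 0.01 at n1=n2=8."""
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 8)
    y = rng.normal(0.5, 1, 8)
    _, p_exact = mann_whitney_u(x, y)  # auto-selects exact (no ties, n<=8)
    p_norm = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
    assert abs(p_exact - p_norm) < 0.01


def test_mann_whitney_empty_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Robust linear regression of absence days
# ---------------------------------------------------------------------------

def test_robust_null_recovery(null_cohort):
    for est in robust_linear_diff(null_cohort, adjusted=True):
        assert est.lcl <= 0 <= est.ucl


def test_robust_constant_outcome_warns(null_cohort):
    df = null_cohort.baseline.copy()
    df["absence_days"] = 5.0
    with pytest.warns(RuntimeWarning, match="zero variance"):
        ests = robust_linear_diff(df)
    assert all(e.estimate == 0.0 for e in ests)


def test_robust_collinear_names_columns(null_cohort):
    df = null_cohort.baseline.copy()
    df["workability"] = 2.0 * df["age"]  # exact linear dependence w/ age
    df["mskhq_0"] = df["age"]
    with pytest.raises(ValueError, match="collinear"):
        robust_linear_diff(df, adjusted=True)


def test_robust_ols_variant_close_to_huber(null_cohort):
    h = robust_linear_diff(null_cohort, estimator="huber")
    o = robust_linear_diff(null_cohort, estimator="ols")
    for eh, eo in zip(h, o):
        assert abs(eh.estimate - eo.estimate) < 15  # same null target


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_events_survival_one():
    km = kaplan_meier(toy_survival([12, 12, 12], [0, 0, 0]))
    assert (km["survival"] == 1.0).all()


def test_km_hand_computed_product_limit():
    """events at 2 and 3, censored at 5 and 12:
    S(3) = (3/4) * (2/3) = 0.5 by hand enumeration."""
    km = kaplan_meier(toy_survival([2, 3, 5, 12], [1, 1, 0, 0]))
    s = km.set_index("month")["survival"]
    assert s[1] == 1.0
    assert np.isclose(s[2], 0.75)
    assert np.isclose(s[3], 0.5)
    assert np.isclose(s[12], 0.5)  # no further events


def test_km_equals_empirical_without_censoring():
    rng = np.random.default_rng(0)
    times = rng.integers(1, 13, size=60)
    km = kaplan_meier(toy_survival(times, np.ones(60, dtype=int)))
    for m in range(1, 13):
        assert np.isclose(km.loc[km["month"] == m, "survival"].iloc[0],
                          (times > m).mean())


def test_km_monotone_in_unit_interval(small_cohort):
    so = survival_outcomes(small_cohort)
    km = kaplan_meier(so)
    s = km["survival"].to_numpy()
    assert ((s >= 0) & (s <= 1)).all()
    assert (np.diff(s) <= 1e-12).all()
    assert (km["lcl"] <= km["survival"] + 1e-12).all()
    assert (km["survival"] <= km["ucl"] + 1e-12).all()


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_oracle(df):
    """Hand enumeration of the two-group O-E/V statistic."""
    times = sorted(df.loc[df["event"] == 1, "time"].unique())
    O = E = V = 0.0
    for t in times:
        at_risk = df[df["time"] >= t]
        n = len(at_risk)
        n1 = (at_risk["arm"] == "B").sum()
        d = ((df["time"] == t) & (df["event"] == 1)).sum()
        d1 = ((df["time"] == t) & (df["event"] == 1) & (df["arm"] == "B")).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_log_rank_identical_groups_zero():
    base = toy_survival([2, 4, 6, 12], [1, 1, 1, 0])
    dup = pd.concat([base.assign(arm="A"), base.assign(arm="B")],
                    ignore_index=True)
    stat, p = log_rank(dup)
    assert stat < 1e-9
    assert p > 0.999


def test_log_rank_hand_enumeration():
    df = toy_survival([1, 3, 5, 2, 4, 12], [1, 1, 0, 1, 1, 0],
                      arms=["A", "A", "A", "B", "B", "B"])
    stat, _ = log_rank(df)
    assert np.isclose(stat, logrank_oracle(df), rtol=1e-6)


def test_log_rank_label_permutation_invariant():
    df = toy_survival([1, 3, 5, 2, 4, 12], [1, 1, 0, 1, 1, 1],
                      arms=["A", "A", "A", "B", "B", "B"])
    stat1, _ = log_rank(df)
    swapped = df.assign(arm=df["arm"].map({"A": "B", "B": "A"}))
    stat2, _ = log_rank(swapped)
    assert np.isclose(stat1, stat2)


def test_log_rank_needs_two_groups():
    with pytest.raises(ValueError):
        log_rank(toy_survival([1, 2], [1, 1]))


def test_log_rank_power_at_moderate_hazard_ratio():
    """With a true monthly hazard ratio of 1.3 and 1000/arm, the log-rank test
    rejects at the 5% level in at least 80% of replicates."""
    from trialecon import ArmSpec, CohortConfig, generate_cohort
    rejections = 0
    n_rep = 25
    for rep in range(n_rep):
        cfg = CohortConfig(arms=[ArmSpec("UC", 1000),
                                 ArmSpec("UC+SVAI", 1000, rtw_hazard_ratio=1.3)],
                           seed=100 + rep, missingness_rates={})
        so = survival_outcomes(generate_cohort(cfg))
        _, p = log_rank(so)
        rejections += p < 0.05
    assert rejections / n_rep >= 0.8


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta, times, events, x):
    """The written partial likelihood for untied data."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def test_cox_brute_force_oracle():
    """5 subjects, 2 groups, no ties: coefficient equals the brute-force
    maximum of the written partial likelihood (grid + golden-section refine)."""
    times = [1, 3, 4, 6, 9]
    events = [1, 1, 1, 1, 0]
    x = [0, 1, 0, 1, 1]
    df = toy_survival(times, events, arms=["UC", "B", "UC", "B", "B"])
    est = cox_ph(df, reference="UC")[0]
    grid = np.linspace(-4, 4, 801)
    best = grid[np.argmax([cox_partial_loglik(b, times, events, x)
                           for b in grid])]
    refined = scipy.optimize.minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bracket=(best - 0.05, best, best + 0.05)).x
    assert abs(np.log(est.estimate) - refined) < 1e-4


def test_cox_all_small_toys_match_oracle():
    """Brute-force partial-likelihood agreement on several <=6-subject toys."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = 6
        times = list(rng.permutation(np.arange(1, n + 1)))  # no ties
        events = list(rng.integers(0, 2, n))
        if sum(events) < 2:
            events[0] = events[1] = 1
        x = list(rng.integers(0, 2, n))
        if len(set(x)) < 2:
            x[0] = 1 - x[0]
        # skip configurations with infinite MLE (monotone likelihood)
        ll = [cox_partial_loglik(b, times, events, x) for b in (-15.0, 15.0)]
        mid = cox_partial_loglik(0.0, times, events, x)
        if max(ll) >= mid:
            continue
        arms = ["B" if xi else "UC" for xi in x]
        df = toy_survival(times, events, arms=arms)
        est = cox_ph(df, reference="UC")[0]
        refined = scipy.optimize.minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x),
            bounds=(-15, 15), method="bounded",
            options={"xatol": 1e-10}).x
        assert abs(np.log(est.estimate) - refined) < 1e-4


def test_cox_null_recovery(null_cohort):
    so = survival_outcomes(null_cohort)
    for est in cox_ph(so, baseline=null_cohort.baseline, adjusted=True):
        assert est.lcl <= 1.0 <= est.ucl


def test_cox_breslow_close_to_efron(small_cohort):
    so = survival_outcomes(small_cohort)
    efron = cox_ph(so, ties="efron")
    breslow = cox_ph(so, ties="breslow")
    for e, b in zip(efron, breslow):
        assert abs(np.log(e.estimate) - np.log(b.estimate)) < 0.15


# ---------------------------------------------------------------------------
# Monthly benefit model
# ---------------------------------------------------------------------------

def _mini_cohort(y_by_arm, months=1):
    """Build a minimal cohort whose panel holds the given benefit outcomes."""
    from trialecon import ArmSpec, CohortConfig, generate_cohort
    n = len(next(iter(y_by_arm.values())))
    cfg = CohortConfig(arms=[ArmSpec(a, n) for a in y_by_arm], seed=1,
                       months=months, missingness_rates={})
    c = generate_cohort(cfg)
    vals = []
    for a in y_by_arm:
        for yi in y_by_arm[a]:
            vals.extend([yi] * months)
    c.panel["benefit_received"] = vals
    return c


def test_benefit_single_month_matches_likelihood_grid():
    """With one month the model is ordinary logistic regression; compare to a
    brute-force maximization of the written Bernoulli likelihood."""
    y0, y1 = [1, 0, 1], [0, 0, 1]
    c = _mini_cohort({"UC": y0, "B": y1})
    est = monthly_benefit_model(c, reference="UC")[0]

    def negll(theta):
        a, b = theta
        ll = 0.0
        for yi in y0:
            p = 1 / (1 + np.exp(-a))
            ll += yi * np.log(p) + (1 - yi) * np.log(1 - p)
        for yi in y1:
            p = 1 / (1 + np.exp(-(a + b)))
            ll += yi * np.log(p) + (1 - yi) * np.log(1 - p)
        return -ll

    grid = [(a, b) for a in np.linspace(-3, 3, 61)
            for b in np.linspace(-4, 4, 81)]
    a0, b0 = min(grid, key=negll)
    refined = scipy.optimize.minimize(negll, [a0, b0], method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12}).x
    assert abs(np.log(est.estimate) - refined[1]) < 1e-3


def test_benefit_identical_arms_or_near_one(null_cohort):
    for est in monthly_benefit_model(null_cohort):
        assert est.lcl <= 1.0 <= est.ucl


def test_benefit_constant_outcome_rejected():
    c = _mini_cohort({"UC": [1, 1, 1], "B": [1, 1, 1]})
    with pytest.raises(ValueError, match="constant"):
        monthly_benefit_model(c)


def test_benefit_gee_variant_covers_null(null_cohort):
    for est in monthly_benefit_model(null_cohort, method="gee"):
        assert est.lcl <= 1.0 <= est.ucl


# ---------------------------------------------------------------------------
# MSK-HQ mixed model
# ---------------------------------------------------------------------------

def test_mixed_model_closed_form_cell_means():
    """Balanced complete two-timepoint data: the arm-at-time contrasts equal
    the plain differences of cell means (closed-form GLS)."""
    rng = np.random.default_rng(2)
    rows = []
    mu = {("UC", 3): 30.0, ("UC", 6): 32.0, ("B", 3): 33.0, ("B", 6): 37.0}
    for arm in ("UC", "B"):
        for i in range(40):
            for t in (3, 6):
                rows.append({"id": f"{arm}{i}", "arm": arm, "time": t,
                             "score": mu[(arm, t)] + rng.normal(0, 2),
                             "mskhq_0": 27.0})
    long = pd.DataFrame(rows)
    ests = mskhq_mixed_model(long, reference="UC", include_baseline=False)
    cell = long.groupby(["arm", "time"])["score"].mean()
    for est in ests:
        t = int(est.comparison.split("@")[1].strip().rstrip("m"))
        expected = cell[("B", t)] - cell[("UC", t)]
        assert abs(est.estimate - expected) < 1e-6


def test_mixed_model_null_interactions(null_cohort):
    for est in mskhq_mixed_model(null_cohort):
        assert est.lcl <= 0 <= est.ucl


def test_mixed_model_unstructured_variant(null_cohort):
    ri = mskhq_mixed_model(null_cohort, covariance="random_intercept")
    un = mskhq_mixed_model(null_cohort, covariance="unstructured")
    for a, b in zip(ri, un):
        assert abs(a.estimate - b.estimate) < 1.5


def test_mixed_model_shift_recovery():
    """A +3-point 12-month MSK-HQ shift is recovered within half a point."""
    from trialecon import ArmSpec, CohortConfig, generate_cohort
    cfg = CohortConfig(arms=[ArmSpec("UC", 2000),
                             ArmSpec("UC+SVAI", 2000, mskhq_shift_12m=3.0)],
                       seed=9, missingness_rates={})
    ests = mskhq_mixed_model(generate_cohort(cfg))
    at12 = [e for e in ests if e.comparison.endswith("12m")][0]
    assert abs(at12.estimate - 3.0) < 0.5


def test_mixed_model_all_absent_rejected(null_cohort):
    df = null_cohort.baseline.copy()
    for t in (3, 6, 9, 12):
        df[f"mskhq_{t}"] = np.nan
    c = Cohort(df, null_cohort.panel, null_cohort.months)
    with pytest.raises(ValueError, match="no post-baseline"):
        mskhq_mixed_model(c)
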