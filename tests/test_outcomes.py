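"""Survival estimators, counting-process Cox models, propensity, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cfcpet import (
    build_counting_process,
    cox_fit,
    fit_propensity,
    group_compare,
    hazard_ratio_curve,
    interaction_model,
    km_estimate,
    log_rank,
)
from cfcpet.errors import AnalysisError, ValidationError
from cfcpet.outcomes import DAYS_PER_YEAR, expand_time_interaction

COVS = ["age", "male", "diabetes", "severe_present"]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def test_km_no_events_is_one():
    curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert np.all(curve.at([0.5, 1.5, 2.5, 3.0]) == 1.0)


def test_km_single_subject_event():
    curve = km_estimate([1.0], [1])
    assert curve.at(0.5) == 1.0
    assert curve.at(1.0) == 0.0
    assert curve.at(2.0) == 0.0


def test_km_matches_manual_product_limit():
    """times 1..5, events 1,0,1,0,1: hand-computed product-limit values."""
    curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
    # t=1: 5 at risk, 1 event -> 4/5; t=3: 3 at risk -> 4/5*2/3; t=5: 1 at risk -> 0
    assert curve.at(1.0) == pytest.approx(0.8)
    assert curve.at(2.5) == pytest.approx(0.8)
    assert curve.at(3.0) == pytest.approx(0.8 * 2 / 3)
    assert curve.at(4.9) == pytest.approx(0.8 * 2 / 3)
    assert curve.at(5.0) == pytest.approx(0.0)


def test_km_all_events_equals_empirical_survival():
    rng = np.random.default_rng(1)
    times = rng.exponential(2.0, 100)
    curve = km_estimate(times, np.ones(100))
    grid = np.quantile(times, [0.1, 0.4, 0.8])
    for t in grid:
        assert curve.at(t) == pytest.approx((times > t).mean())


def test_km_rejects_empty_and_nonpositive():
    with pytest.raises(ValidationError):
        km_estimate([], [])
    with pytest.raises(ValidationError):
        km_estimate([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_log_rank_identical_groups_zero():
    t = [1, 2, 3, 4, 5]
    e = [1, 0, 1, 1, 0]
    stat, p = log_rank(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_log_rank_label_permutation_invariant():
    ta, ea = [1, 3, 5, 7], [1, 1, 0, 1]
    tb, eb = [2, 4, 6], [1, 0, 1]
    s1, _ = log_rank(ta, ea, tb, eb)
    s2, _ = log_rank(tb, eb, ta, ea)
    assert s1 == pytest.approx(s2)


def test_log_rank_matches_observed_minus_expected_oracle():
    ta, ea = np.array([1.0, 2, 4, 6, 8]), np.array([1, 1, 0, 1, 0])
    tb, eb = np.array([3.0, 5, 7, 9, 10]), np.array([1, 0, 1, 1, 1])
    # brute-force O-E/V at each distinct event time
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.r_[np.zeros(5), np.ones(5)]
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat, _ = log_rank(ta, ea, tb, eb)
    assert stat == pytest.approx(o_minus_e ** 2 / var, rel=1e-9)


def test_log_rank_no_events_undefined():
    with pytest.raises(AnalysisError):
        log_rank([1, 2], [0, 0], [3, 4], [0, 0])


# ---------------------------------------------------------------------------
# Counting process
# ---------------------------------------------------------------------------

def one_scan(rev90, rev_day, fup, event=1, time=None):
    return pd.DataFrame({
        "scan_id": [0], "patient_id": [0],
        "revasc90": [rev90], "revascularization_day": [rev_day],
        "followup_years": [fup],
        "dms_time": [fup if time is None else time], "dms_event": [event],
        "severe_present": [1],
    })


def test_untreated_scan_single_unexposed_row():
    cp = build_counting_process(one_scan(0, np.nan, 2.0, event=0))
    assert len(cp) == 1
    assert cp.loc[0, ["start", "stop", "exposed", "event"]].tolist() == \
        [0.0, 2.0, 0, 0]


def test_treated_scan_splits_at_revascularization_day():
    cp = build_counting_process(one_scan(1, 30.0, 3.0))
    t_rev = 30.0 / DAYS_PER_YEAR
    assert len(cp) == 2
    assert cp.loc[0, ["start", "stop", "exposed", "event"]].tolist() == \
        pytest.approx([0.0, t_rev, 0, 0])
    assert cp.loc[1, ["start", "stop", "exposed", "event"]].tolist() == \
        pytest.approx([t_rev, 3.0, 1, 1])


def test_late_revascularization_never_exposes():
    cp = build_counting_process(one_scan(1, 120.0, 3.0))
    assert len(cp) == 1
    assert (cp["exposed"] == 0).all()


def test_revascularization_after_followup_rejected():
    with pytest.raises(ValidationError):
        build_counting_process(one_scan(1, 80.0, 0.1))


def test_split_conserves_at_risk_time(small_cohort):
    cohort, _ = small_cohort
    cp = build_counting_process(cohort, outcome="dms", covariates=COVS)
    per_scan = cp.groupby("scan_id").apply(
        lambda g: (g["stop"] - g["start"]).sum(), include_groups=False)
    expected = cohort.set_index("scan_id")["dms_time"]
    np.testing.assert_allclose(per_scan[expected.index], expected, rtol=1e-12)
    # events land once, on the final row of each scan
    assert cp.groupby("scan_id")["event"].sum().equals(
        cohort.set_index("scan_id")["dms_event"].rename("event"))


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------

def toy_cox_data(n=40, beta=0.8, seed=2):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.5 * np.exp(beta * x)))
    c = rng.exponential(2.0, n)
    df = pd.DataFrame({"scan_id": np.arange(n), "start": 0.0,
                       "stop": np.minimum(t, c), "event": (t <= c).astype(int),
                       "x": x})
    return df


def partial_loglik(df, beta):
    """Written-out tie-free Cox partial likelihood (independent oracle)."""
    x = df["x"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    start = df["start"].to_numpy(float)
    ll = 0.0
    for i in np.flatnonzero(df["event"].to_numpy() == 1):
        at_risk = (start < stop[i]) & (stop >= stop[i])
        ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def test_cox_small_instance_matches_grid_oracle():
    df = toy_cox_data()
    fit = cox_fit(df, ["x"])
    grid = np.arange(-3, 3, 0.001)
    lls = np.array([partial_loglik(df, b) for b in grid])
    assert fit.params["x"] == pytest.approx(grid[lls.argmax()], abs=2e-3)
    # fitted likelihood dominates every grid point
    assert partial_loglik(df, fit.params["x"]) >= lls.max() - 1e-9


def test_cox_null_covariate_ci_covers_one(small_cohort):
    cohort, _ = small_cohort
    cohort = cohort.copy()
    rng = np.random.default_rng(8)
    cohort["noise"] = rng.normal(size=len(cohort))
    cp = build_counting_process(cohort, outcome="dms",
                                covariates=COVS + ["noise"])
    fit = cox_fit(cp, COVS + ["noise", "exposed"])
    # single seeded draw: check absence of gross bias at the 99% level
    ci = fit.conf_int(alpha=0.01).loc["noise"]
    assert ci["hr_lower"] < 1.0 < ci["hr_upper"]
    assert abs(fit.params["noise"]) < 0.2


def test_efron_equals_breslow_on_tie_free_data():
    df = toy_cox_data(n=60, seed=3)
    assert df["stop"].nunique() == len(df)  # tie-free by construction
    fe = cox_fit(df, ["x"], ties="efron")
    fb = cox_fit(df, ["x"], ties="breslow")
    assert fe.params["x"] == pytest.approx(fb.params["x"], abs=1e-8)
    assert fe.log_likelihood == pytest.approx(fb.log_likelihood, abs=1e-8)


def test_cox_rank_deficiency_and_no_events_error():
    df = toy_cox_data()
    df["x2"] = df["x"]
    with pytest.raises(AnalysisError, match="alias|rank"):
        cox_fit(df, ["x", "x2"])
    df["c"] = 1.0
    with pytest.raises(AnalysisError, match="constant"):
        cox_fit(df, ["x", "c"])
    dead = df.assign(event=0)
    with pytest.raises(AnalysisError, match="event"):
        cox_fit(dead, ["x"])


# ---------------------------------------------------------------------------
# Propensity
# ---------------------------------------------------------------------------

def test_propensity_null_scores_equal_prevalence():
    rng = np.random.default_rng(4)
    n = 4000
    df = pd.DataFrame({"age": rng.normal(60, 10, n),
                       "male": rng.integers(0, 2, n),
                       "revasc90": (rng.random(n) < 0.1).astype(int)})
    model = fit_propensity(df, ["age", "male"])
    assert model.scores.mean() == pytest.approx(df["revasc90"].mean(), abs=1e-6)
    assert np.all((model.scores > 0) & (model.scores < 1))


def test_propensity_recovers_known_logistic_model():
    rng = np.random.default_rng(5)
    n = 8000
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n)
    logit = -2.0 + 0.8 * x1 + 0.5 * x2
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = pd.DataFrame({"x1": x1, "x2": x2, "revasc90": y.astype(int)})
    model = fit_propensity(df, ["x1", "x2"])
    for name, truth in (("const", -2.0), ("x1", 0.8), ("x2", 0.5)):
        assert abs(model.params[name] - truth) < 1.96 * model.se[name] + 1e-9


def test_propensity_requires_both_arms():
    df = pd.DataFrame({"age": [1.0, 2.0], "revasc90": [0, 0]})
    with pytest.raises(AnalysisError):
        fit_propensity(df, ["age"])


# ---------------------------------------------------------------------------
# Interaction model and hazard-ratio curve
# ---------------------------------------------------------------------------

def test_interaction_model_structure_and_sign(small_cohort):
    cohort, truth = small_cohort
    cp = build_counting_process(cohort, outcome="dms", covariates=COVS)
    fit = interaction_model(cp, COVS)
    assert len(fit.params) == len(COVS) + 2  # base + exposure + product
    # the generator benefits only the severe stratum: negative interaction
    coef = fit.params["exposed:severe_present"]
    assert coef < 0
    true_inter = np.log(truth.hr_revasc_severe) - np.log(truth.hr_revasc_nonsevere)
    assert abs(coef - true_inter) < 1.96 * fit.se["exposed:severe_present"]


def test_hazard_ratio_curve_flat_under_ph(small_cohort):
    cohort, _ = small_cohort
    cp = build_counting_process(cohort, outcome="dms", covariates=COVS)
    fit = cox_fit(cp, COVS + ["exposed"])
    curve = hazard_ratio_curve(fit, cp)
    assert curve["hazard_ratio"].nunique() == 1
    assert curve["hazard_ratio"].iloc[0] == pytest.approx(
        np.exp(fit.params["exposed"]))


def test_time_varying_effect_direction_recovered():
    """Hazard h(t|x=1) = lam * t^(-0.5): exposure HR declines in time; the
    exposure-by-log-time expansion recovers the negative slope."""
    rng = np.random.default_rng(6)
    n, lam = 4000, 0.3
    x = rng.integers(0, 2, n)
    e = rng.exponential(1.0, n)
    t = np.where(x == 1, (e / (2 * lam)) ** 2, e / lam)
    c = np.minimum(rng.exponential(4.0, n), 6.0)
    df = pd.DataFrame({"scan_id": np.arange(n), "start": 0.0,
                       "stop": np.minimum(t, c), "event": (t <= c).astype(int),
                       "exposed": x})
    grid = np.quantile(df.loc[df["event"] == 1, "stop"],
                       np.linspace(0.05, 0.95, 16))
    expanded = expand_time_interaction(df, grid)
    fit = cox_fit(expanded, ["exposed", "exposed:logt"])
    assert fit.params["exposed:logt"] < 0  # declining benefit, matching truth
    assert fit.p_values["exposed:logt"] < 0.01
    curve = hazard_ratio_curve(fit, expanded,
                               time_grid=np.linspace(0.2, 4.0, 10))
    assert (np.diff(curve["hazard_ratio"]) < 0).all()


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def test_group_compare_identical_groups_p_one():
    df = pd.DataFrame({"g": [0] * 10 + [1] * 10,
                       "b": [0, 1] * 10,
                       "c": list(range(10)) * 2})
    out = group_compare(df, "g").set_index("variable")
    assert out.loc["b", "statistic"] == 0.0
    assert out.loc["b", "p"] == 1.0
    assert out.loc["c", "p"] == 1.0


def test_welch_t_matches_hand_formula():
    a = np.array([17.8, 18.5, 19.6, 20.4, 19.8, 18.9])
    b = np.array([21.2, 24.1, 19.9, 23.3, 25.2])
    df = pd.DataFrame({"g": [0] * 6 + [1] * 5, "v": np.r_[a, b]})
    out = group_compare(df, "g").set_index("variable")
    # Welch statistic and Satterthwaite df written out from the formulas
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
    assert out.loc["v", "statistic"] == pytest.approx(t_hand, rel=1e-9)
    assert out.loc["v", "p"] == pytest.approx(p_hand, rel=1e-6)


def test_group_compare_reports_printed_proportions():
    """116/134 vs 2,694/3,640 male -> 87% vs 74%, a significant difference."""
    g = np.r_[np.ones(134), np.zeros(3640)]
    male = np.r_[np.ones(116), np.zeros(18), np.ones(2694), np.zeros(946)]
    out = group_compare(pd.DataFrame({"revasc90": g, "male": male}),
                        "revasc90").set_index("variable")
    assert round(out.loc["male", "group_b_stat"]) == 87
    assert round(out.loc["male", "group_a_stat"]) == 74
    assert out.loc["male", "p"] < 0.05


def test_group_compare_needs_two_groups():
    with pytest.raises(ValidationError):
        group_compare(pd.DataFrame({"g": [1, 1], "v": [1.0, 2.0]}), "g")
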