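"""Weighted partial-likelihood engine, sandwich variance and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import wcohort as wc
from wcohort.cox import ModelSpec, build_design

from conftest import random_survival_frame


def naive_weighted_loglik(beta, df, xcol="x1", wcol=None):
    """Definitional weighted partial log-likelihood (Breslow), double loop."""
    w = df[wcol].to_numpy() if wcol else np.ones(len(df))
    t, e, x = (df["exit_age"].to_numpy(), df["event"].to_numpy(),
               df[xcol].to_numpy())
    ll = 0.0
    for i in range(len(df)):
        if e[i]:
            rs = t >= t[i]
            ll += w[i] * (x[i] * beta
                          - np.log(np.sum(w[rs] * np.exp(x[rs] * beta))))
    return ll


SIX = pd.DataFrame({
    "exit_age": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
    "event": [1, 1, 0, 1, 0, 0],
    "x1": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    "family_id": [1, 2, 3, 4, 5, 6],
})


def test_six_subject_fixture_matches_brute_force():
    res = minimize_scalar(lambda b: -naive_weighted_loglik(b, SIX),
                          bracket=(-3, 0, 3), method="golden",
                          options={"xtol": 1e-12})
    f = wc.fit(SIX, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    assert f.params["x1"] == pytest.approx(res.x, abs=1e-6)
    assert f.loglik == pytest.approx(naive_weighted_loglik(f.params["x1"], SIX),
                                     abs=1e-10)


def test_duplicating_subjects_equals_doubling_weights():
    rng = np.random.default_rng(1)
    df = random_survival_frame(rng, 40)
    dup = pd.concat([df, df.assign(family_id=df["family_id"] + 1000)],
                    ignore_index=True)
    f_dup = wc.fit(dup, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    f_w = wc.fit(df.assign(weight=2.0),
                 ModelSpec(exposure="custom", exposure_cols=("x1",)),
                 weight_col="weight")
    assert f_dup.params["x1"] == pytest.approx(f_w.params["x1"], abs=1e-10)


def test_robust_matches_lifelines_cluster_sandwich():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    df = random_survival_frame(rng, 150, n_covs=2)
    f = wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1", "x2")))
    cph = lifelines.CoxPHFitter()
    cph.fit(df.rename(columns={"exit_age": "T", "event": "E"}),
            duration_col="T", event_col="E", cluster_col="family_id",
            robust=True, fit_options={"precision": 1e-10})
    assert np.allclose(f.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6)
    assert np.allclose(f.robust_se.to_numpy(),
                       cph.standard_errors_.to_numpy(), rtol=1e-5)


def test_singleton_clusters_give_textbook_sandwich():
    rng = np.random.default_rng(6)
    df = random_survival_frame(rng, 80, n_covs=2)
    df["family_id"] = np.arange(len(df))          # one subject per family
    f = wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1", "x2")))
    U = f.score_residuals[["x1", "x2"]].to_numpy()
    A_inv = f.naive_cov.to_numpy()
    V = A_inv @ (U.T @ U) @ A_inv
    assert np.allclose(f.robust_cov.to_numpy(), V, atol=1e-12)
    assert abs(U.sum(axis=0)).max() < 1e-8        # residuals sum to the score


def test_family_duplication_scales_robust_variance_exactly():
    rng = np.random.default_rng(7)
    df = random_survival_frame(rng, 60)
    k = 3
    rep = pd.concat([df.assign(family_id=df["family_id"] + 1000 * j)
                     for j in range(k)], ignore_index=True)
    f1 = wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    fk = wc.fit(rep, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    assert fk.robust_cov.iloc[0, 0] * k == pytest.approx(
        f1.robust_cov.iloc[0, 0], rel=1e-10)


def test_robust_covariance_is_symmetric_psd():
    rng = np.random.default_rng(8)
    df = random_survival_frame(rng, 120, n_covs=3)
    f = wc.fit(df, ModelSpec(exposure="custom",
                             exposure_cols=("x1", "x2", "x3")))
    V = f.robust_cov.to_numpy()
    assert np.allclose(V, V.T)
    assert np.linalg.eigvalsh(V).min() > -1e-12
    s = f.summary()
    assert ((s["hr_ci_low"] <= s["hr"]) & (s["hr"] <= s["hr_ci_high"])).all()


def test_newton_never_decreases_loglik():
    rng = np.random.default_rng(9)
    for _ in range(10):
        df = random_survival_frame(rng, 50, n_covs=2, weights=True)
        f = wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1", "x2")),
                   weight_col="weight")
        assert all(b >= a - 1e-12 for a, b in zip(f.trace, f.trace[1:]))
        assert f.converged


def test_hazard_ratio_invariant_to_covariate_recoding(carrier_records):
    inc = wc.default_carrier_incidence()
    rec = wc.assign_weights(carrier_records,
                            wc.compute_weights(carrier_records, inc), inc)
    rec["z"] = (rec["smoke20"] == "ever").astype(float)
    rec["z_recoded"] = 10.0 * rec["z"] - 3.0
    a = wc.fit(rec, ModelSpec(exposure="bmi5", covariates=("sex", "z")),
               weight_col="weight")
    b = wc.fit(rec, ModelSpec(exposure="bmi5", covariates=("sex", "z_recoded")),
               weight_col="weight")
    assert a.params["bmi5"] == pytest.approx(b.params["bmi5"], abs=1e-8)


def test_efron_ties_match_statsmodels():
    sm = pytest.importorskip("statsmodels.duration.hazard_regression")
    rng = np.random.default_rng(10)
    df = random_survival_frame(rng, 120, n_covs=2)
    df["exit_age"] = np.ceil(df["exit_age"] * 4) / 4          # create ties
    for ties in ("breslow", "efron"):
        f = wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1", "x2"),
                                 ties=ties))
        ph = sm.PHReg(df["exit_age"], df[["x1", "x2"]], status=df["event"],
                      ties=ties).fit()
        assert np.allclose(f.params.to_numpy(), ph.params, atol=1e-5), ties


def test_separation_is_detected():
    df = pd.DataFrame({
        "exit_age": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
        "event": [1, 1, 1, 0, 0, 0],
        "x1": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        "family_id": range(6),
    })
    with pytest.raises(wc.ConvergenceError) as err:
        wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    assert err.value.separation
    assert len(err.value.trace) > 1


def test_requires_two_distinct_event_ages_and_varying_covariates():
    df = SIX.assign(event=[1, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="distinct event ages"):
        wc.fit(df, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    df2 = SIX.assign(x1=1.0)
    with pytest.raises(ValueError, match="constant"):
        wc.fit(df2, ModelSpec(exposure="custom", exposure_cols=("x1",)))


def test_schoenfeld_residual_series_structure():
    f = wc.fit(SIX, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    assert len(f.schoenfeld) == 3                  # one row per event
    assert list(f.schoenfeld["event_age"]) == [2.0, 3.0, 5.0]
    two = SIX.assign(event=[1, 1, 0, 0, 0, 0])
    f2 = wc.fit(two, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    assert len(f2.schoenfeld) == 2


def test_schoenfeld_test_detects_reversing_hazard():
    """A hazard ratio that flips sign mid-follow-up must be flagged, while a
    proportional one should not be (power check at ~2000 events)."""
    rng = np.random.default_rng(11)

    def simulate(reverse):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        beta = 0.7
        t0 = 0.7
        t1 = rng.exponential(np.exp(-beta * x))
        if reverse:
            extra = rng.exponential(np.exp(beta * x))
            t = np.where(t1 < t0, t1, t0 + extra)
        else:
            t = t1
        return pd.DataFrame({"exit_age": t, "event": 1,
                             "x1": x, "family_id": np.arange(n)})

    hits = 0
    for _ in range(5):
        f = wc.fit(simulate(True), ModelSpec(exposure="custom",
                                             exposure_cols=("x1",)))
        hits += wc.schoenfeld_test(f).loc["x1", "p"] < 0.05
    assert hits >= 3

    f = wc.fit(simulate(False), ModelSpec(exposure="custom",
                                          exposure_cols=("x1",)))
    res = wc.schoenfeld_test(f)
    assert {"chi2", "df", "p"} <= set(res.columns)


def test_schoenfeld_test_preconditions():
    f = wc.fit(SIX, ModelSpec(exposure="custom", exposure_cols=("x1",)))
    with pytest.raises(ValueError, match="at least 10 events"):
        wc.schoenfeld_test(f)


def test_interaction_test_symmetric_in_term_order(carrier_records):
    inc = wc.default_carrier_incidence()
    rec = wc.assign_weights(carrier_records,
                            wc.compute_weights(carrier_records, inc), inc)
    spec = ModelSpec(exposure="bmi5", covariates=("sex", "smoke20"))
    s1, df1, p1, _ = wc.wald_interaction(rec, spec, ("sex", "bmi5"),
                                         weight_col="weight")
    s2, df2, p2, _ = wc.wald_interaction(rec, spec, ("bmi5", "sex"),
                                         weight_col="weight")
    assert s1 == s2 and df1 == df2 and p1 == p2
    with pytest.raises(ValueError, match="main effect"):
        wc.wald_interaction(rec, spec, ("alcohol20", "bmi5"))


def test_design_matrix_reference_levels(carrier_records):
    X, groups = build_design(carrier_records,
                             ModelSpec(exposure="who_category",
                                       covariates=("sex", "country")))
    assert "who_normal" not in X.columns          # normal weight is referent
    assert set(groups["who_category"]) <= {"who_underweight", "who_overweight",
                                           "who_obese"}
    assert "country_ANZ" not in X.columns         # first level is referent
    assert X["sex"].isin([0.0, 1.0]).all()
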