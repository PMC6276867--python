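"""Cox engine validation against independent oracles.

The primary oracle maximizes the explicitly written-out partial likelihood
by generic numerical optimization (scipy) on small hand-written datasets;
lifelines serves as an independent reference implementation on simulated
data, including robust clustered standard errors and Efron ties.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import cflandmark as cf
from cflandmark.survival import (
    ConvergenceError,
    CoxModelSpec,
    RankDeficiencyError,
    StepFunction,
    TermSpec,
    TimeBasis,
    breslow_baseline,
    fit_cox,
    fit_from_json,
    fit_to_json,
    predict_survival,
    predict_survival_at,
)


def brute_force_partial_loglik(beta, times, events, X, time_funcs=None):
    """The Cox partial log-likelihood written out directly (no ties)."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in np.flatnonzero(events):
        t = times[i]
        risk = times >= t
        if time_funcs is None:
            f = np.ones(len(beta))
        else:
            f = np.array([1.0 if g is None else g(t) for g in time_funcs])
        eta = X[risk] @ (beta * f)
        eta_i = X[i] @ (beta * f)
        ll += eta_i - np.log(np.sum(np.exp(eta)))
    return ll


def brute_force_fit(times, events, X, time_funcs=None):
    p = X.shape[1]
    res = optimize.minimize(
        lambda b: -brute_force_partial_loglik(b, times, events, X, time_funcs),
        np.zeros(p),
        method="BFGS",
        options={"gtol": 1e-12},
    )
    return res.x


# five hand-written datasets: <=8 subjects, 1-2 covariates, no ties
HAND_DATASETS = [
    # (times, events, X)
    ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 0, 1, 1, 0, 1], [[0], [1], [1], [0], [1], [0]]),
    ([2.5, 1.2, 3.7, 0.8, 5.1, 4.4], [1, 1, 0, 1, 1, 0], [[0.5], [-1.2], [2.0], [0.1], [-0.4], [1.3]]),
    (
        [1, 2, 3, 4, 5, 6, 7, 8],
        [1, 1, 1, 0, 1, 0, 1, 1],
        [[0, 1], [1, 0], [1, 1], [0, 0], [0.5, -1], [1, 2], [-1, 0.5], [0.2, 0.8]],
    ),
    ([0.5, 1.5, 2.5, 3.5, 4.5], [1, 1, 1, 1, 0], [[1.0], [0.0], [2.0], [-1.0], [0.5]]),
    (
        [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3],
        [0, 1, 1, 1, 0, 1, 1],
        [[1, -1], [0, 0], [1, 1], [-1, 0], [0, 1], [0.5, 0.5], [-0.5, 1.5]],
    ),
]


def _df(times, events, X):
    X = np.asarray(X, dtype=float)
    d = pd.DataFrame({"time": times, "event": events, "patient_id": np.arange(len(times))})
    for j in range(X.shape[1]):
        d[f"x{j}"] = X[:, j]
    return d, X


@pytest.mark.parametrize("case", range(len(HAND_DATASETS)))
def test_coefficients_match_brute_force_maximization(case):
    times, events, X = HAND_DATASETS[case]
    df, X = _df(times, events, X)
    spec = CoxModelSpec(terms=tuple(TermSpec(f"x{j}", f"x{j}") for j in range(X.shape[1])))
    fit = fit_cox(df, spec, center=False)
    beta_oracle = brute_force_fit(np.asarray(times, float), np.asarray(events, bool), X)
    assert np.allclose(fit.beta, beta_oracle, atol=1e-6)
    # the reported maximum satisfies first-order optimality of the written-out likelihood
    eps = 1e-5
    for j in range(len(fit.beta)):
        e = np.zeros(len(fit.beta))
        e[j] = eps
        deriv = (
            brute_force_partial_loglik(fit.beta + e, np.asarray(times), np.asarray(events, bool), X)
            - brute_force_partial_loglik(fit.beta - e, np.asarray(times), np.asarray(events, bool), X)
        ) / (2 * eps)
        assert abs(deriv) < 1e-4
    assert fit.loglik >= fit.loglik_null


def test_centering_does_not_change_coefficients():
    times, events, X = HAND_DATASETS[2]
    df, X = _df(times, events, X)
    spec = CoxModelSpec(terms=(TermSpec("x0", "x0"), TermSpec("x1", "x1")))
    f0 = fit_cox(df, spec, center=False)
    f1 = fit_cox(df, spec, center=True)
    assert np.allclose(f0.beta, f1.beta, atol=1e-9)
    assert np.allclose(f0.robust_covariance, f1.robust_covariance, atol=1e-9)


def test_null_model_baseline_is_nelson_aalen():
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 1, 1, 0, 1, 0],
            "patient_id": range(6),
            "g": [0, 0, 0, 1, 1, 1],
        }
    )
    fit = fit_cox(df, CoxModelSpec(terms=(), strata="g"))
    # stratum 0: events at 1 (n=3), 2 with d=2 (n=2): H = 1/3, 1/3+1
    h0 = fit.baseline_cumhaz[0]
    assert np.allclose(h0.x, [1.0, 2.0])
    assert np.allclose(h0.y, [1 / 3, 1 / 3 + 2 / 2])
    # stratum 1: event at 4 among 2 at risk
    h1 = fit.baseline_cumhaz[1]
    assert np.allclose(h1.x, [4.0])
    assert np.allclose(h1.y, [1 / 2])


def test_breslow_baseline_hand_computed():
    df = pd.DataFrame(
        {"time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [0.0, 1.0, 0.5], "patient_id": range(3)}
    )
    spec = CoxModelSpec(terms=(TermSpec("x", "x"),))
    beta = np.array([0.5])
    sf = breslow_baseline(df, spec, beta, centering=np.zeros(1))
    w = np.exp(0.5 * np.array([0.0, 1.0, 0.5]))
    inc1 = 1.0 / w.sum()
    inc2 = 1.0 / w[1:].sum()
    assert np.allclose(sf.x, [1.0, 2.0])
    assert np.allclose(sf.y, [inc1, inc1 + inc2])


def test_single_subject_death_jumps_by_one():
    df = pd.DataFrame({"time": [3.0], "event": [1], "patient_id": [0]})
    fit = fit_cox(df, CoxModelSpec(terms=()))
    sf = fit.baseline_cumhaz[None]
    assert np.allclose(sf.x, [3.0]) and np.allclose(sf.y, [1.0])


def test_duplication_halves_naive_but_not_robust():
    times, events, X = HAND_DATASETS[0]
    df, _ = _df(times, events, X)
    spec = CoxModelSpec(terms=(TermSpec("x0", "x0"),), cluster="patient_id")
    base = fit_cox(df, spec)
    dup = pd.concat([df, df], ignore_index=True)  # same patient_id in both copies
    fit2 = fit_cox(dup, spec)
    assert np.allclose(fit2.beta, base.beta, atol=1e-8)
    assert np.allclose(fit2.naive_covariance, base.naive_covariance / 2, rtol=1e-6)
    assert np.allclose(fit2.robust_covariance, base.robust_covariance, rtol=1e-6)


def test_affine_rescaling_invariance():
    times, events, X = HAND_DATASETS[1]
    df, _ = _df(times, events, X)
    spec = CoxModelSpec(terms=(TermSpec("x0", "x0"),))
    f0 = fit_cox(df, spec)
    df2 = df.copy()
    df2["x0"] = 10.0 * df2["x0"] + 3.0
    f1 = fit_cox(df2, spec)
    assert f1.beta[0] * 10.0 == pytest.approx(f0.beta[0], abs=1e-7)
    assert f1.loglik == pytest.approx(f0.loglik, abs=1e-8)


def test_one_stratum_equals_unstratified(small_stacked):
    sub = small_stacked.records[small_stacked.records["L"] == 25.0].reset_index(drop=True)
    spec_u = CoxModelSpec(terms=(TermSpec("fev1_pct", "fev1_pct"), TermSpec("weight", "weight")))
    sub2 = sub.assign(const_stratum=1)
    spec_s = CoxModelSpec(terms=spec_u.terms, strata="const_stratum")
    fu = fit_cox(sub, spec_u)
    fs = fit_cox(sub2, spec_s)
    assert np.allclose(fu.beta, fs.beta, atol=1e-10)
    assert fu.loglik == pytest.approx(fs.loglik, abs=1e-9)


def test_rank_deficiency_names_columns():
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0],
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [2.0, 4.0, 6.0, 8.0],
            "patient_id": range(4),
        }
    )
    spec = CoxModelSpec(terms=(TermSpec("a", "a"), TermSpec("b", "b")))
    with pytest.raises(RankDeficiencyError, match="b"):
        fit_cox(df, spec)


def test_zero_event_stratum_warns_flat_baseline():
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 0, 0],
            "g": [0, 0, 1, 1],
            "x": [0.1, 0.9, 0.4, 0.6],
            "patient_id": range(4),
        }
    )
    with pytest.warns(UserWarning, match="no events"):
        fit = fit_cox(df, CoxModelSpec(terms=(TermSpec("x", "x"),), strata="g"))
    assert len(fit.baseline_cumhaz[1].x) == 0


@pytest.fixture(scope="module")
def sim_records(ph_stacked):
    return ph_stacked.records[ph_stacked.records["L"].isin([25.0, 30.0])].reset_index(drop=True)


class TestAgainstLifelines:
    def test_breslow_coefficients_and_baseline(self, sim_records):
        from lifelines import CoxPHFitter

        cols = ["fev1_pct", "weight", "pseudomonas", "sex"]
        spec = CoxModelSpec(terms=tuple(TermSpec(c, c) for c in cols), strata="L")
        fit = fit_cox(sim_records, spec)
        cph = CoxPHFitter()
        cph.fit(
            sim_records[cols + ["time", "event", "L"]],
            duration_col="time",
            event_col="event",
            strata=["L"],
        )
        assert np.allclose(fit.beta, cph.params_[cols].values, atol=2e-5)

    def test_robust_clustered_se(self, sim_records):
        from lifelines import CoxPHFitter

        cols = ["fev1_pct", "weight"]
        spec = CoxModelSpec(terms=tuple(TermSpec(c, c) for c in cols), strata="L", cluster="patient_id")
        fit = fit_cox(sim_records, spec)
        cph = CoxPHFitter()
        cph.fit(
            sim_records[cols + ["time", "event", "L", "patient_id"]],
            duration_col="time",
            event_col="event",
            strata=["L"],
            cluster_col="patient_id",
            robust=True,
        )
        assert np.allclose(fit.robust_se, cph.standard_errors_[cols].values, rtol=2e-3)

    def test_efron_ties_match(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(np.exp(-0.6 * x)) * 4)  # heavy ties
        e = rng.random(n) < 0.7
        df = pd.DataFrame({"time": t + 1, "event": e.astype(int), "x": x, "patient_id": range(n)})
        fit = fit_cox(df, CoxModelSpec(terms=(TermSpec("x", "x"),), ties="efron"))
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        cph.fit(df[["time", "event", "x"]], "time", "event")  # lifelines uses Efron
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=2e-6)


def test_fast_and_loop_score_residuals_agree(sim_records):
    """Without ties, Breslow and Efron coincide, so the cumulative-sum
    residual path and the event-loop path must give the same sandwich."""
    sub = sim_records.drop_duplicates("time").reset_index(drop=True)
    cols = ["fev1_pct", "weight"]
    terms = tuple(TermSpec(c, c) for c in cols)
    fb = fit_cox(sub, CoxModelSpec(terms=terms, strata="L", cluster="patient_id", ties="breslow"))
    fe = fit_cox(sub, CoxModelSpec(terms=terms, strata="L", cluster="patient_id", ties="efron"))
    assert np.allclose(fb.beta, fe.beta, atol=1e-8)
    assert np.allclose(fb.robust_covariance, fe.robust_covariance, rtol=1e-6)


class TestTimeVaryingTerms:
    def test_time_interaction_matches_brute_force(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1], dtype=bool)
        X = np.array([[0.5], [-1.0], [0.2], [1.5], [-0.3], [0.8], [0.0]])
        df = pd.DataFrame(
            {"time": times, "event": events.astype(int), "x": X[:, 0], "patient_id": range(7)}
        )
        tb = TimeBasis(kind="linear", scale=10.0)
        spec = CoxModelSpec(
            terms=(TermSpec("x", "x"), TermSpec("x:t", "x", time_basis=tb))
        )
        fit = fit_cox(df, spec, center=False)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        beta_oracle = brute_force_fit(times, events, X2, time_funcs=[None, lambda t: t / 10.0])
        assert np.allclose(fit.beta, beta_oracle, atol=1e-6)

    def test_prediction_accumulates_over_jumps(self):
        # a time-varying fit must integrate exp(lp(u)) dH0(u), not multiply
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 0],
                "x": [0.5, -0.5, 1.0, 0.0, -1.0, 0.3],
                "patient_id": range(6),
            }
        )
        tb = TimeBasis(kind="linear", scale=10.0)
        spec = CoxModelSpec(terms=(TermSpec("x", "x"), TermSpec("x:t", "x", time_basis=tb)))
        fit = fit_cox(df, spec)
        H0 = fit.baseline_cumhaz[None]
        xval = 0.7
        xc = xval - fit.centering[0]
        dH = np.diff(np.concatenate([[0.0], H0.y]))
        expected_H = sum(
            dh * np.exp(fit.beta[0] * xc + fit.beta[1] * xc * (t / 10.0)) for t, dh in zip(H0.x, dH)
        )
        curve = predict_survival(fit, {"x": xval}, times=np.array([6.0]))
        assert curve.survival[0] == pytest.approx(np.exp(-expected_H), abs=1e-10)
        vec = predict_survival_at(fit, pd.DataFrame({"x": [xval]}), 6.0)
        assert vec[0] == pytest.approx(np.exp(-expected_H), abs=1e-10)


class TestPrediction:
    def test_survival_curve_properties(self, ph_stacked):
        sub = ph_stacked.records[ph_stacked.records["L"] == 30.0].reset_index(drop=True)
        spec = CoxModelSpec(terms=(TermSpec("fev1_pct", "fev1_pct"), TermSpec("weight", "weight")))
        fit = fit_cox(sub, spec)
        curve = predict_survival(fit, {"fev1_pct": 60.0, "weight": 50.0})
        assert curve.survival[0] == 1.0 or curve.times[0] == 0.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_reference_profile_gives_baseline(self, ph_stacked):
        sub = ph_stacked.records[ph_stacked.records["L"] == 30.0].reset_index(drop=True)
        spec = CoxModelSpec(terms=(TermSpec("fev1_pct", "fev1_pct"),))
        fit = fit_cox(sub, spec)
        ref = {"fev1_pct": fit.centering[0]}  # zero linear predictor
        curve = predict_survival(fit, ref, times=np.array([5.0]))
        assert curve.survival[0] == pytest.approx(np.exp(-fit.baseline_cumhaz[None](5.0)), abs=1e-12)

    def test_unknown_stratum_suggests_nearest(self, ph_stacked):
        spec = CoxModelSpec(terms=(TermSpec("fev1_pct", "fev1_pct"),), strata="L")
        fit = fit_cox(ph_stacked.records, spec)
        with pytest.raises(KeyError, match="nearest"):
            predict_survival(fit, {"fev1_pct": 70.0}, L=99.0)

    def test_serialization_roundtrip_preserves_predictions(self, ph_stacked):
        spec = CoxModelSpec(
            terms=(TermSpec("fev1_pct", "fev1_pct"), TermSpec("weight", "weight")), strata="L"
        )
        fit = fit_cox(ph_stacked.records, spec)
        back = fit_from_json(fit_to_json(fit))
        prof = {"fev1_pct": 55.0, "weight": 48.0}
        c1 = predict_survival(fit, prof, L=30.0)
        c2 = predict_survival(back, prof, L=30.0)
        assert np.allclose(c1.survival, c2.survival, atol=1e-12)
        assert np.allclose(back.robust_se, fit.robust_se)
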