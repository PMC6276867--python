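"""Evaluation metrics against brute-force and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cflandmark as cf
from cflandmark.evaluation import (
    UndefinedMetricError,
    _censoring_survival,
    brier_score,
    c_index,
    calibration_table,
    evaluate_predictions,
    kaplan_meier,
    km_reference_predictions,
    km_survival_at,
    monte_carlo_cv,
    percent_reduction,
    split_stacked,
)
from cflandmark.landmark import StackedDataset
from cflandmark.variants import VariantOptions, fit_variant


def c_index_bruteforce(risk, time, event, horizon):
    """Exhaustive pair enumeration oracle for the truncated C-index."""
    t = np.minimum(np.asarray(time, float), horizon)
    e = np.asarray(event, bool) & (np.asarray(time) <= horizon)
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j])):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError
    return num / den


class TestCIndex:
    def test_perfect_ordering_gives_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert c_index(risk, time, event, 10.0) == 1.0

    def test_all_ties_give_half(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        risk = np.zeros(4)
        assert c_index(risk, time, event, 10.0) == 0.5

    def test_hand_case_with_censoring(self):
        time = np.array([2.0, 3.0, 3.0, 5.0])
        event = np.array([1, 0, 1, 0])
        risk = np.array([0.9, 0.1, 0.8, 0.2])
        assert c_index(risk, time, event, 10.0) == pytest.approx(
            c_index_bruteforce(risk, time, event, 10.0)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        time = np.round(rng.exponential(5, n), 1) + 0.1
        event = rng.random(n) < 0.7
        risk = np.round(rng.normal(size=n), 1)  # rounded: force ties
        horizon = float(rng.choice([2.0, 5.0, 10.0]))
        try:
            expected = c_index_bruteforce(risk, time, event, horizon)
        except ZeroDivisionError:
            with pytest.raises(UndefinedMetricError):
                c_index(risk, time, event, horizon)
            return
        assert c_index(risk, time, event, horizon) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(5, 50)
        event = rng.random(50) < 0.6
        risk = rng.normal(size=50)
        a = c_index(risk, time, event, 5.0)
        b = c_index(np.exp(3 * risk) + 7, time, event, 5.0)
        assert a == pytest.approx(b)

    def test_truncation_ignores_late_events(self):
        time = np.array([1.0, 3.0, 6.0, 7.0])
        event = np.array([1, 0, 1, 1])  # events after horizon 5 are censored at 5
        risk = np.array([1.0, 0.0, 5.0, 4.0])
        assert c_index(risk, time, event, 5.0) == pytest.approx(
            c_index_bruteforce(risk, time, event, 5.0)
        )


class TestBrier:
    def test_perfect_predictions_no_censoring(self):
        time = np.array([1.0, 2.0, 8.0, 9.0])
        event = np.array([1, 1, 1, 1])
        pred = np.array([0.0, 0.0, 1.0, 1.0])  # S(5): first two die before 5
        assert brier_score(pred, time, event, 5.0) == 0.0

    def test_constant_half_no_censoring(self):
        time = np.array([1.0, 2.0, 8.0, 9.0])
        event = np.array([1, 1, 1, 1])
        assert brier_score(np.full(4, 0.5), time, event, 5.0) == pytest.approx(0.25)

    def test_hand_computed_ipcw_sum(self):
        # 6 records, horizon 5.  Censoring KM: censored at 2 (5 at risk) and
        # at 4 (3 at risk) -> G = 1 on [0,2), 4/5 on [2,4), 8/15 on [4,7).
        time = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0])
        event = np.array([1, 0, 1, 0, 1, 0])
        pred = np.array([0.2, 0.9, 0.4, 0.6, 0.8, 0.7])
        w = np.array([1.0, 0.0, 1 / (4 / 5), 0.0, 1 / (8 / 15), 1 / (8 / 15)])
        ind = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])  # censored rows have weight 0
        expected = np.sum(w * (ind - pred) ** 2) / np.sum(w)
        assert brier_score(pred, time, event, 5.0) == pytest.approx(expected)

    def test_no_censoring_equals_plain_mse(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(6, 40)
        event = np.ones(40, dtype=int)
        pred = rng.random(40)
        h = 5.0
        mse = np.mean(((time > h).astype(float) - pred) ** 2)
        assert brier_score(pred, time, event, h) == pytest.approx(mse)

    def test_zero_censoring_survival_raises(self):
        from cflandmark.survival import StepFunction

        # an externally supplied censoring distribution that hits zero
        g = StepFunction(np.array([0.5]), np.array([0.0]), initial=1.0)
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])
        with pytest.raises(ValueError, match="horizon|censoring"):
            brier_score(np.array([0.5, 0.5, 0.5]), time, event, 5.0, censoring_sf=g)


def test_percent_reduction_arithmetic():
    assert percent_reduction(0.1, 0.1) == 0.0
    assert percent_reduction(0.075, 0.100) == pytest.approx(25.0)
    assert percent_reduction(0.12, 0.10) == pytest.approx(-20.0)
    with pytest.raises(ValueError):
        percent_reduction(0.1, 0.0)


class TestKaplanMeier:
    def test_single_event_among_two(self):
        sf = kaplan_meier([2.0, 3.0], [1, 0])
        assert sf(2.0) == 0.5

    def test_no_events_is_one(self):
        assert km_survival_at([1.0, 2.0, 3.0], [0, 0, 0], 2.5) == 1.0

    def test_hand_computed_products(self):
        # events at 1 (5 at risk), 3 (3 at risk); censored at 2, 4, 5
        sf = kaplan_meier([1.0, 2.0, 3.0, 4.0, 5.0], [1, 0, 1, 0, 0])
        assert sf(1.0) == pytest.approx(4 / 5)
        assert sf(3.5) == pytest.approx(4 / 5 * 2 / 3)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        time = np.ceil(rng.exponential(5, 100))
        event = rng.random(100) < 0.6
        sf = kaplan_meier(time, event)
        km = KaplanMeierFitter().fit(time, event)
        for t in [1.0, 2.0, 5.0, 8.0]:
            assert sf(t) == pytest.approx(km.predict(t), abs=1e-10)

    def test_censoring_distribution_flips_indicator(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])
        g = _censoring_survival(time, event)
        assert g(2.0) == pytest.approx(0.5)  # one censoring among 2 at risk

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestSplit:
    def test_full_fraction_gives_empty_holdout(self, small_stacked):
        train, hold = split_stacked(small_stacked, 1.0, seed=0)
        assert len(hold) == 0 and len(train) == len(small_stacked)

    def test_deterministic_under_seed(self, small_stacked):
        a = split_stacked(small_stacked, 0.8, seed=5)
        b = split_stacked(small_stacked, 0.8, seed=5)
        pd.testing.assert_frame_equal(a[0].records, b[0].records)

    def test_partition_and_patient_level(self, small_stacked):
        train, hold = split_stacked(small_stacked, 0.8, seed=1)
        assert len(train) + len(hold) == len(small_stacked)
        overlap = set(train.records["patient_id"]) & set(hold.records["patient_id"])
        assert not overlap

    def test_per_landmark_share_near_fraction(self):
        reg = cf.simulate_registry(cf.default_config(3000, seed=17))
        stacked = cf.build_stacked_dataset(reg)
        train, hold = split_stacked(stacked, 0.8, seed=2)
        counts = train.records.groupby("L").size()
        totals = stacked.records.groupby("L").size()
        share = (counts / totals).dropna()
        big = share[totals >= 400]
        assert (abs(big - 0.8) < 0.05).all()
        assert abs(len(train) / len(stacked) - 0.8) < 0.02

    def test_record_unit_exact_stratification(self, small_stacked):
        train, hold = split_stacked(small_stacked, 0.8, seed=3, unit="record")
        for L, total in small_stacked.records.groupby("L").size().items():
            got = (train.records["L"] == L).sum()
            assert abs(got - round(0.8 * total)) <= 1


class TestCalibrationAndCV:
    def test_constant_predictions_single_group(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(8, 200)
        event = np.ones(200)
        cal = calibration_table(np.full(200, 0.6), time, event, 5.0)
        assert len(cal.table) == 1
        assert cal.table["observed"].iloc[0] == pytest.approx(np.mean(time > 5.0))

    def test_one_group_is_overall_km(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(8, 300)
        event = rng.random(300) < 0.7
        pred = rng.random(300)
        cal = calibration_table(pred, time, event, 5.0, n_groups=1)
        assert len(cal.table) == 1
        assert cal.table["observed"].iloc[0] == pytest.approx(km_survival_at(time, event, 5.0))
        assert cal.table["mean_predicted"].iloc[0] == pytest.approx(pred.mean())

    def test_outcomes_drawn_from_predictions_are_calibrated(self):
        """When true outcomes are generated from the predicted survival
        probabilities, decile calibration points must sit on the identity
        line within binomial noise."""
        rng = np.random.default_rng(5)
        n = 4000
        pred = rng.uniform(0.3, 0.99, n)
        h = 5.0
        # exponential event times matching S(h) = pred exactly, no censoring
        lam = -np.log(pred) / h
        time = rng.exponential(1 / lam)
        event = np.ones(n)
        cal = calibration_table(pred, time, event, h)
        tab = cal.table
        dev = np.abs(tab["observed"] - tab["mean_predicted"])
        se = np.sqrt(tab["mean_predicted"] * (1 - tab["mean_predicted"]) / tab["n"])
        assert (dev < 3 * se + 1e-9).sum() >= len(tab) - 1

    def test_monte_carlo_cv_smoke_and_failure_guards(self, ph_stacked):
        sub = StackedDataset(
            ph_stacked.records[ph_stacked.records["L"].isin([25.0, 30.0, 35.0])].reset_index(drop=True),
            [25.0, 30.0, 35.0],
        )
        opts = VariantOptions(variant=2)
        preds = ["fev1_pct", "weight", "pseudomonas"]
        report = monte_carlo_cv(
            sub, lambda d: fit_variant(d, opts, predictors=preds), n_reps=3, seed=9
        )
        assert report.cv_summary is not None
        assert 0.5 < report.overall["c_index_5yr"] <= 1.0
        with pytest.raises(ValueError):
            monte_carlo_cv(sub, lambda d: None, n_reps=0)

    def test_pooled_equals_per_landmark_when_single_L(self, ph_stacked):
        sub = ph_stacked.records[ph_stacked.records["L"] == 30.0].reset_index(drop=True)
        opts = VariantOptions(variant=2)
        preds = ["fev1_pct", "weight", "pseudomonas"]
        fit = fit_variant(StackedDataset(sub, [30.0]), opts, predictors=preds)
        report = cf.evaluate_fit(fit, sub)
        for h in ["c_index_5yr", "brier_5yr"]:
            assert report.overall[h] == pytest.approx(report.per_landmark[h].iloc[0])


def test_km_reference_predictions_per_landmark(small_stacked):
    ref = km_reference_predictions(small_stacked.records, [5.0])
    r = small_stacked.records
    for L in [20.0, 30.0]:
        idx = np.flatnonzero(r["L"].to_numpy() == L)
        if len(idx) == 0:
            continue
        expected = km_survival_at(r["time"].iloc[idx], r["event"].iloc[idx], 5.0)
        assert np.allclose(ref[5.0][idx], expected)
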