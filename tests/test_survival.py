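"""Feature selection cascade, Cox modelling, concordance, and the G index."""

import numpy as np
import pandas as pd
import pytest

from radrobust.phantom import simulate_survival
from radrobust.survival import (
    CoxRiskModel,
    SurvivalDataset,
    bootstrap_c,
    c_index,
    feature_number_sweep,
    fit_final_model,
    g_index,
    lasso_frequency_select,
    preselect_by_icc,
    run_threshold_experiment,
    univariate_screen,
)


def brute_force_c(time, event, risk):
    """All-pairs Harrell concordance (independent O(n^2) oracle)."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def _databank(rows):
    df = pd.DataFrame(rows, columns=["feature_name", "family", "mean_icc", "class_label"])
    df["image_type"] = "original"
    return df.set_index("feature_name")


def _sim_dataset(n, n_noise, beta, seed, censor_rate=0.03):
    rng = np.random.default_rng(seed)
    names = list(beta) + [f"noise{i:02d}" for i in range(n_noise)]
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    out = simulate_survival(X, beta, censor_rate=censor_rate, seed=seed + 1)
    return SurvivalDataset("sim", X, out)


class TestPreselect:
    def _bank(self):
        return _databank(
            [
                ("f_a", "firstorder", 0.95, "excellent"),
                ("f_b", "glcm", 0.86, "good"),
                ("f_c", "glrlm", 0.6, "moderate"),
                ("f_d", "ngtdm", 0.3, "poor"),
                ("original_shape_MeshVolume", "shape", 0.99, "excellent"),
                ("f_e", "glszm", float("nan"), "degenerate"),
            ]
        )

    def test_thresholds_are_nested_and_strict(self):
        bank = self._bank()
        sels = [preselect_by_icc(bank, t) for t in (0.9, 0.85, 0.8, 0.75, 0.5, None)]
        for hi, lo in zip(sels, sels[1:]):
            assert set(hi) <= set(lo)
        assert preselect_by_icc(bank, 0.95) == []  # strict inequality

    def test_shape_and_degenerate_always_excluded(self):
        sel = preselect_by_icc(self._bank(), None)
        assert "original_shape_MeshVolume" not in sel
        assert "f_e" not in sel
        assert sel == ["f_a", "f_b", "f_c", "f_d"]

    def test_impossible_threshold_returns_empty(self):
        assert preselect_by_icc(self._bank(), 1.0) == []


class TestUnivariateScreen:
    def test_strong_effect_retained_pure_noise_mostly_dropped(self):
        ds = _sim_dataset(400, 20, {"signal": 1.0}, seed=0)
        kept = univariate_screen(ds, list(ds.features.columns))
        assert "signal" in kept
        assert len(kept) <= 5  # ~5% of 20 noise features plus the signal

    def test_empty_candidates_gives_empty_result(self):
        ds = _sim_dataset(100, 2, {"signal": 1.0}, seed=1)
        assert univariate_screen(ds, []) == []

    def test_too_few_events_rejected(self):
        ds = _sim_dataset(30, 2, {"signal": 1.0}, seed=2, censor_rate=50.0)
        with pytest.raises(ValueError, match="events"):
            univariate_screen(ds, ["signal"])


class TestCoxRiskModel:
    def test_refit_is_deterministic(self):
        ds = _sim_dataset(200, 3, {"signal": 1.0}, seed=3)
        a = fit_final_model(ds, ["signal", "noise00"])
        b = fit_final_model(ds, ["signal", "noise00"])
        assert np.array_equal(a.coef_, b.coef_)

    def test_beta_recovery_within_15pct(self):
        ds = _sim_dataset(2000, 1, {"signal": 1.0}, seed=4, censor_rate=0.0)
        model = fit_final_model(ds, ["signal"])
        assert model.coef_[0] == pytest.approx(1.0, rel=0.15)

    def test_missing_feature_rejected(self):
        ds = _sim_dataset(100, 1, {"signal": 1.0}, seed=5)
        with pytest.raises(KeyError):
            fit_final_model(ds, ["absent"])

    def test_empty_selection_rejected(self):
        ds = _sim_dataset(100, 1, {"signal": 1.0}, seed=6)
        with pytest.raises(ValueError, match="empty"):
            fit_final_model(ds, [])

    def test_collinear_features_still_fit(self):
        ds = _sim_dataset(150, 1, {"signal": 1.0}, seed=7)
        ds.features["dup"] = ds.features["signal"]
        model = fit_final_model(ds, ["signal", "dup"])
        assert np.isfinite(model.coef_).all()


class TestCIndex:
    def test_matches_bruteforce_all_pairs(self, rng):
        n = 30
        time = rng.exponential(10, n)
        event = rng.random(n) < 0.7
        risk = rng.normal(size=n)
        X = pd.DataFrame({"r": risk})
        y = pd.DataFrame({"time": time, "event": event.astype(int)})
        model = CoxRiskModel(features=["r"]).fit(X, y)
        # force the model's risk ordering to equal the raw scores
        model.coef_ = np.array([1.0])
        model.mean_ = np.array([0.0])
        model.scale_ = np.array([1.0])
        got = c_index(model, SurvivalDataset("t", X, y))
        assert got == pytest.approx(brute_force_c(time, event.astype(int), risk), abs=1e-12)

    def test_constant_risk_is_half(self):
        X = pd.DataFrame({"r": np.zeros(20)})
        y = pd.DataFrame({"time": np.arange(1.0, 21.0), "event": np.ones(20, int)})
        model = CoxRiskModel(["r"]).fit(X, y)
        model.coef_ = np.array([1.0])
        assert c_index(model, SurvivalDataset("t", X, y)) == 0.5

    def test_perfect_risk_order_is_one(self, rng):
        t = rng.exponential(5, 40) + 0.1
        X = pd.DataFrame({"r": -t})
        y = pd.DataFrame({"time": t, "event": np.ones(40, int)})
        model = CoxRiskModel(["r"]).fit(X, y)
        model.coef_, model.mean_, model.scale_ = np.array([1.0]), np.array([0.0]), np.array([1.0])
        assert c_index(model, SurvivalDataset("t", X, y)) == 1.0


class TestBootstrapC:
    def test_summary_over_requested_replicates(self):
        ds = _sim_dataset(120, 1, {"signal": 1.0}, seed=8)
        model = fit_final_model(ds, ["signal"])
        mean, (lo, hi), samples = bootstrap_c(model, ds, n_boot=100, seed=0)
        assert len(samples) == 100
        assert lo <= mean <= hi

    def test_reproducible(self):
        ds = _sim_dataset(80, 1, {"signal": 1.0}, seed=9)
        model = fit_final_model(ds, ["signal"])
        assert bootstrap_c(model, ds, 50, seed=1)[:2] == bootstrap_c(model, ds, 50, seed=1)[:2]

    def test_single_patient_cohort_rejected(self):
        ds = _sim_dataset(100, 1, {"signal": 1.0}, seed=10)
        model = fit_final_model(ds, ["signal"])
        tiny = ds.subset([0])
        with pytest.raises(ValueError):
            bootstrap_c(model, tiny, 10, seed=0)


class TestGIndex:
    def test_hand_arithmetic(self):
        assert g_index(0.8, [0.7, 0.6]) == pytest.approx(0.15)

    def test_zero_gap(self):
        assert g_index(0.7, [0.7, 0.7]) == 0.0

    def test_permutation_invariant_and_nonnegative(self, rng):
        evs = list(rng.uniform(0.4, 0.9, 5))
        a = g_index(0.75, evs)
        b = g_index(0.75, evs[::-1])
        assert a == b >= 0

    def test_empty_ev_list_rejected(self):
        with pytest.raises(ValueError):
            g_index(0.7, [])


class TestLassoFrequencySelect:
    def test_two_signals_recovered_in_top_five(self):
        ds = _sim_dataset(500, 50, {"sig_a": 1.0, "sig_b": 1.0}, seed=11)
        top, trace = lasso_frequency_select(
            ds, list(ds.features.columns), n_bootstraps=10, k=5, seed=0
        )
        assert len(top) == 5
        assert {"sig_a", "sig_b"} <= set(top)
        assert len(trace.bootstrap_selections) == 10

    def test_empty_candidates_rejected(self):
        ds = _sim_dataset(100, 2, {"s": 1.0}, seed=12)
        with pytest.raises(ValueError):
            lasso_frequency_select(ds, [], 5, 5, 0)


class TestThresholdExperiment:
    def test_six_thresholds_give_six_reports(self):
        ds = _sim_dataset(300, 30, {"sig_a": 1.0, "sig_b": 0.8}, seed=13)
        rows = [("sig_a", "firstorder", 0.95, "excellent"),
                ("sig_b", "firstorder", 0.92, "excellent")]
        rows += [(f"noise{i:02d}", "glcm", 0.2 + 0.02 * i, "poor") for i in range(30)]
        bank = _databank(rows)
        evs = [_sim_dataset(150, 30, {"sig_a": 1.0, "sig_b": 0.8}, seed=14)]
        evs[0].cohort_name = "EV1"
        reports = run_threshold_experiment(
            bank, ds, evs, thresholds=(0.9, 0.85, 0.8, 0.75, 0.5, None),
            n_boot_eval=25, seed=0,
        )
        assert len(reports) == 6
        for rep in reports.values():
            assert 0 <= rep.c_train[0] <= 1
            assert rep.g_mean >= 0
            assert set(rep.features) <= set(rep.trace.survivors_after_univariate)
            assert set(rep.trace.survivors_after_univariate) <= set(
                rep.trace.survivors_after_icc
            )

    def test_identical_distributions_give_small_g(self):
        ds = _sim_dataset(800, 2, {"sig_a": 1.0}, seed=15)
        ev = _sim_dataset(800, 2, {"sig_a": 1.0}, seed=16)
        bank = _databank([("sig_a", "firstorder", 0.95, "excellent")])
        reports = run_threshold_experiment(
            bank, ds, [ev], thresholds=(None,), n_boot_eval=25, seed=1
        )
        assert reports[None].g_mean < 0.05

    def test_empty_pool_raises(self):
        ds = _sim_dataset(100, 2, {"sig_a": 1.0}, seed=17)
        bank = _databank([("sig_a", "firstorder", 0.4, "poor")])
        with pytest.raises(ValueError, match="no candidate"):
            run_threshold_experiment(bank, ds, [ds], thresholds=(0.9,), seed=0)


class TestFeatureNumberSweep:
    def test_rows_and_train_c_monotone(self):
        ds = _sim_dataset(300, 10, {"sig_a": 1.0, "sig_b": 1.0}, seed=18)
        test = _sim_dataset(150, 10, {"sig_a": 1.0, "sig_b": 1.0}, seed=19)
        sweep = feature_number_sweep(
            ds, test, list(ds.features.columns), k_range=range(1, 7), seed=0
        )
        assert len(sweep) == 6
        assert (np.diff(sweep["c_train"]) > -0.01).all()
        # test C plateaus once the true signal dimension (2) is reached
        c2 = sweep.loc[sweep["k"] == 2, "c_test"].iloc[0]
        assert c2 >= sweep["c_test"].max() - 0.02
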