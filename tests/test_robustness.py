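"""One-way ICC, resampling, classification, and the databank assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radrobust.robustness import (
    build_databank,
    classify_icc,
    default_sample_sizes,
    icc_oneway,
    resampled_icc,
    sample_size_curve,
    top_variance_features,
)


def brute_force_oneway_icc(x: np.ndarray, variant: str = "shrout_fleiss") -> float:
    """Explicit sum-of-squares loops: the independent ANOVA oracle."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    ssb = 0.0
    ssw = 0.0
    for i in range(n):
        row_mean = sum(x[i]) / k
        ssb += k * (row_mean - grand) ** 2
        for j in range(k):
            ssw += (x[i][j] - row_mean) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    mult = (k - 1) if variant == "shrout_fleiss" else (k + 1)
    return (msb - msw) / (msb + mult * msw)


def _random_effects_table(n_patients, k, n_features, icc_target, seed):
    """Long-format feature table with known between/within variance split."""
    rng = np.random.default_rng(seed)
    sigma_b = math.sqrt(icc_target)
    sigma_w = math.sqrt(1 - icc_target)
    cols = {}
    for f in range(n_features):
        subject = rng.normal(0, sigma_b, size=(n_patients, 1))
        cols[f"feat{f}"] = (subject + rng.normal(0, sigma_w, size=(n_patients, k))).ravel()
    idx = pd.MultiIndex.from_product(
        [[f"P{i:03d}" for i in range(n_patients)],
         ["unperturbed"] + [f"r{j:03d}" for j in range(k - 1)]],
        names=["patient", "measurement"],
    )
    return pd.DataFrame(cols, index=idx)


class TestIccOneway:
    def test_perfect_agreement(self):
        assert icc_oneway([[1, 1], [2, 2], [3, 3]]) == 1.0

    def test_no_between_patient_variance_hand_anova(self):
        x = [[1, 2], [1, 2], [1, 2]]
        assert icc_oneway(x) == pytest.approx(-1.0)
        # paper-literal denominator: (0 - 0.5) / (0 + 3 * 0.5)
        assert icc_oneway(x, "paper_literal") == pytest.approx(-1.0 / 3.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            x = rng.normal(size=(10, 5))
            for variant in ("shrout_fleiss", "paper_literal"):
                assert icc_oneway(x, variant) == pytest.approx(
                    brute_force_oneway_icc(x, variant), abs=1e-10
                )

    def test_constant_matrix_is_nan(self):
        assert math.isnan(icc_oneway(np.full((4, 3), 2.0)))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway([[1, 2]])
        with pytest.raises(ValueError):
            icc_oneway([[1], [2]])

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError, match="variant"):
            icc_oneway(rng.normal(size=(3, 3)), "icc21")

    @settings(max_examples=30, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_location_scale_invariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).normal(size=(6, 4))
        base = icc_oneway(x)
        assert icc_oneway(scale * x + shift) == pytest.approx(base, abs=1e-8)


class TestResampledIcc:
    def test_perfect_matrix_gives_unit_interval(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 4))
        mean, lo, hi = resampled_icc(x, n_patients=4, n_rounds=10, seed=0)
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(size=(20, 6))
        a = resampled_icc(x, 10, 20, seed=3)
        b = resampled_icc(x, 10, 20, seed=3)
        assert a == b

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {10: [], 40: []}
        for rep in range(10):
            table = _random_effects_table(50, 6, 1, icc_target=0.7, seed=rep)
            x = table["feat0"].to_numpy().reshape(50, 6)
            for n in widths:
                _, lo, hi = resampled_icc(x, n, n_rounds=30, seed=rep)
                widths[n].append(hi - lo)
        assert np.mean(widths[40]) < np.mean(widths[10])

    def test_oversized_subsample_rejected(self, rng):
        with pytest.raises(ValueError):
            resampled_icc(rng.normal(size=(5, 3)), n_patients=6)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.49, "poor"),
            (0.5, "moderate"),
            (0.74, "moderate"),
            (0.75, "good"),
            (0.9, "good"),
            (0.91, "excellent"),
            (float("nan"), "degenerate"),
            (-0.3, "poor"),
        ],
    )
    def test_boundaries(self, icc, label):
        assert classify_icc(icc) == label


class TestBuildDatabank:
    def test_one_record_per_feature_and_reproducible(self):
        table = _random_effects_table(12, 5, 4, 0.8, seed=1)
        a = build_databank(table, n_patients_per_resample=8, seed=2)
        b = build_databank(table, n_patients_per_resample=8, seed=2)
        assert len(a) == 4
        pd.testing.assert_frame_equal(a, b)
        assert a["ci_low"].le(a["mean_icc"]).all()
        assert a["mean_icc"].le(a["ci_high"]).all()

    def test_high_icc_table_classified_excellent(self):
        table = _random_effects_table(30, 8, 2, 0.99, seed=3)
        db = build_databank(table, n_patients_per_resample=20, seed=0)
        assert (db["class_label"] == "excellent").all()

    def test_missing_realization_raises_with_gap_listed(self):
        table = _random_effects_table(6, 4, 2, 0.8, seed=4)
        broken = table.drop(index=[("P002", "r001")])
        with pytest.raises(ValueError, match="P002"):
            build_databank(broken)

    def test_degenerate_feature_retained_with_label(self):
        table = _random_effects_table(6, 4, 2, 0.8, seed=5)
        table.loc[("P001", "r000"), "feat1"] = np.nan
        with pytest.warns(UserWarning, match="degenerate"):
            db = build_databank(table)
        assert db.loc["feat1", "class_label"] == "degenerate"
        assert db.loc["feat0", "class_label"] != "degenerate"

    def test_image_type_and_family_parsed(self):
        table = _random_effects_table(5, 3, 1, 0.8, seed=6)
        table.columns = ["wavelet-LLH_glszm_ZoneEntropy_30_binCount"]
        db = build_databank(table)
        assert db.iloc[0]["image_type"] == "wavelet-LLH"
        assert db.iloc[0]["family"] == "glszm"


class TestSampleSizeCurve:
    def test_default_size_grid(self):
        assert default_sample_sizes(300) == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 300]
        assert default_sample_sizes(45) == [10, 20, 30, 40]

    def test_rounds_and_shape(self):
        table = _random_effects_table(30, 5, 3, 0.7, seed=7)
        curve = sample_size_curve(table, sizes=[10, 20], n_rounds=10, seed=0)
        assert len(curve) == 2 * 10 * 3
        per = curve.groupby(["feature", "n"]).size()
        assert (per == 10).all()

    def test_icc_spread_shrinks_with_n(self):
        table = _random_effects_table(60, 6, 5, 0.7, seed=8)
        curve = sample_size_curve(table, sizes=[10, 50], n_rounds=15, seed=1)
        spread = curve.groupby(["feature", "n"])["icc"].std().groupby("n").mean()
        assert spread[50] < spread[10]

    def test_oversized_grid_rejected(self):
        table = _random_effects_table(20, 4, 1, 0.7, seed=9)
        with pytest.raises(ValueError):
            sample_size_curve(table, sizes=[10, 30])


class TestTopVarianceFeatures:
    def _curve(self):
        rows = []
        for n in (10, 20, 30):
            rows += [("steady", n, 0, 0.8), ("drifting", n, 0, 0.5 + 0.01 * n)]
        return pd.DataFrame(rows, columns=["feature", "n", "round", "icc"])

    def test_varying_feature_ranks_first(self):
        assert top_variance_features(self._curve(), 1) == ["drifting"]

    def test_constant_feature_ranks_last(self):
        assert top_variance_features(self._curve(), 2)[-1] == "steady"

    def test_overlong_request_rejected(self):
        with pytest.raises(ValueError):
            top_variance_features(self._curve(), 3)
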