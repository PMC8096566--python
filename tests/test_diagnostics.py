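import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breakcurve as bc
from breakcurve.diagnostics import (
    classify_domain,
    compute_stats,
    hat_diagonals,
    hat_matrix,
    standardized_residuals,
    warning_leverage,
)


class TestComputeStats:
    def test_perfect_fit(self):
        y = np.array([0.1, 0.4, 0.9])
        s = compute_stats(y, y)
        assert (s.r2, s.mae, s.rmse, s.mse, s.aad_percent, s.std_resid) == (
            1.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        )

    def test_two_point_worked_example(self):
        s = compute_stats([0.5, 0.7], [0.4, 0.8])
        assert s.mae == pytest.approx(0.1, abs=1e-15)
        assert s.mse == pytest.approx(0.01, abs=1e-15)
        assert s.rmse == pytest.approx(0.1, abs=1e-15)
        assert s.aad_percent == pytest.approx(10.0, abs=1e-13)
        assert s.r2 == pytest.approx(0.75, abs=1e-15)  # 1 - 0.02/0.08

    def test_constant_prediction_at_mean_gives_zero_r2(self, rng):
        observed = rng.random(20)
        s = compute_stats(np.full(20, observed.mean()), observed)
        assert s.r2 == pytest.approx(0.0, abs=1e-12)

    def test_mse_is_rmse_squared(self, rng):
        s = compute_stats(rng.random(30), rng.random(30))
        assert s.mse == pytest.approx(s.rmse**2, abs=1e-12)

    def test_degenerate_observed_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_stats([0.1, 0.2], [0.5, 0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_stats([0.1], [0.1, 0.2])

    def test_std_as_printed_variant_measures_prediction_spread(self):
        pred = np.array([0.2, 0.8])
        obs = np.array([0.4, 0.6])
        s = compute_stats(pred, obs, std_as_printed=True)
        assert s.std_resid == pytest.approx(np.sqrt(np.mean((pred - 0.5) ** 2)))

    @given(
        shift=st.floats(-10, 10),
        scale=st.floats(0.1, 10),
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_shift_and_scale_invariances(self, shift, scale):
        rng = np.random.default_rng(0)
        pred = rng.random(15)
        obs = rng.random(15)
        base = compute_stats(pred, obs)
        shifted = compute_stats(pred + shift, obs + shift)
        assert shifted.mae == pytest.approx(base.mae, rel=1e-9, abs=1e-12)
        assert shifted.rmse == pytest.approx(base.rmse, rel=1e-9, abs=1e-12)
        assert shifted.std_resid == pytest.approx(base.std_resid, rel=1e-9, abs=1e-12)
        scaled = compute_stats(scale * pred, scale * obs)
        assert scaled.mae == pytest.approx(scale * base.mae, rel=1e-9)
        assert scaled.rmse == pytest.approx(scale * base.rmse, rel=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, rel=1e-9)


class TestHatMatrix:
    def test_single_column_hand_example(self):
        # X = [1, 2]^T, XtX = 5 → H = [[0.2, 0.4], [0.4, 0.8]]
        H = hat_matrix(np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(H, [[0.2, 0.4], [0.4, 0.8]], atol=1e-14)
        assert np.trace(H) == pytest.approx(1.0)

    def test_orthonormal_columns_give_uniform_leverage(self):
        # columns of a DFT-like orthonormal basis: h_ii = k/n, trace = k
        n, k = 8, 3
        Q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(n, k)))
        h = hat_diagonals(Q)
        np.testing.assert_allclose(np.sum(h), k, atol=1e-10)
        H = hat_matrix(Q)
        np.testing.assert_allclose(H, Q @ Q.T, atol=1e-12)

    def test_matches_qr_projector_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        H = hat_matrix(X)
        Q, _ = np.linalg.qr(X)
        np.testing.assert_allclose(H, Q @ Q.T, atol=1e-10)

    def test_projection_properties_on_random_matrices(self, rng):
        for _ in range(5):
            X = rng.normal(size=(rng.integers(5, 30), rng.integers(1, 5)))
            H = hat_matrix(X)
            np.testing.assert_allclose(H, H.T, atol=1e-10)
            np.testing.assert_allclose(H @ H, H, atol=1e-8)
            h = np.diag(H)
            assert np.all(h >= -1e-12) and np.all(h <= 1 + 1e-12)
            assert np.trace(H) == pytest.approx(np.linalg.matrix_rank(X), abs=1e-8)

    def test_rank_deficient_falls_back_to_pseudoinverse(self, rng):
        x = rng.normal(size=(10, 1))
        X = np.hstack([x, 2 * x])  # rank 1
        H = hat_matrix(X)
        np.testing.assert_allclose(H @ H, H, atol=1e-8)
        assert np.trace(H) == pytest.approx(1.0, abs=1e-8)


class TestWarningLeverage:
    def test_paper_scale_counts(self):
        assert warning_leverage(4, 204) == pytest.approx(15.0 / 204)

    def test_edge_and_homogeneity(self):
        assert warning_leverage(0, 3) == pytest.approx(1.0)
        assert warning_leverage(4, 100) == pytest.approx(2 * warning_leverage(4, 200))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            warning_leverage(4, 0)


class TestStandardizedResiduals:
    def test_zero_residuals_give_zeros(self):
        y = np.array([0.1, 0.5, 0.9])
        r = standardized_residuals(y, y, np.zeros(3))
        np.testing.assert_array_equal(r, 0.0)

    def test_zero_leverage_reduces_to_plain_standardization(self, rng):
        pred = rng.random(10)
        obs = rng.random(10)
        e = obs - pred
        s = np.sqrt(np.mean(e**2))
        r = standardized_residuals(pred, obs, np.zeros(10))
        np.testing.assert_allclose(r, e / s, atol=1e-14)

    def test_matches_hand_loop(self, rng):
        pred = rng.random(10)
        obs = rng.random(10)
        h = rng.uniform(0, 0.5, size=10)
        r = standardized_residuals(pred, obs, h)
        e = obs - pred
        s = np.sqrt(np.mean(e**2))
        expected = [ei / (s * np.sqrt(1 - hi)) for ei, hi in zip(e, h)]
        np.testing.assert_allclose(r, expected, atol=1e-12)

    def test_exact_leverage_point_rejected(self):
        with pytest.raises(ValueError, match="h_ii"):
            standardized_residuals([0.1, 0.2], [0.2, 0.1], [0.5, 1.0])


class TestClassifyDomain:
    def test_all_points_in_domain_for_good_fit(self, rng):
        X = rng.normal(size=(50, 4))
        obs = rng.random(50)
        pred = obs + rng.normal(0, 0.01, 50)
        report = classify_domain(pred, obs, X)
        counts = report.counts()
        assert sum(counts.values()) == 50  # every point exactly one label
        assert report.warning_leverage == pytest.approx(15.0 / 50)

    def test_gross_residual_flagged_as_outlier(self, rng):
        X = rng.normal(size=(40, 4))
        obs = rng.random(40)
        pred = obs + rng.normal(0, 0.01, 40)
        obs = obs.copy()
        obs[7] += 1.0  # one gross outlier
        report = classify_domain(pred, obs, X)
        assert report.flags[7] == "outlier_residual"
        assert report.counts()["outlier_residual"] == 1

    def test_extreme_point_has_high_leverage(self, rng):
        X = rng.normal(size=(40, 4))
        X[3] = 50.0  # far outside the cloud
        obs = rng.random(40)
        pred = obs + rng.normal(0, 0.05, 40)
        report = classify_domain(pred, obs, X)
        assert report.flags[3] in ("high_leverage", "both")

    def test_flags_partition_the_points(self, rng):
        X = rng.normal(size=(60, 4))
        obs = rng.random(60)
        pred = rng.random(60)
        report = classify_domain(pred, obs, X)
        assert sum(report.counts().values()) == 60
        assert report.n_outside == 60 - report.counts()["in_domain"]
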