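"""Geographically weighted regression: kernels, local fits, AICc, bandwidth."""

import warnings

import numpy as np
import pytest

from canopyscale.gwr import (
    GWRConfig,
    OversmoothingError,
    aicc_score,
    fit_gwr,
    kernel_weights,
    predict_grid,
    predict_gwr,
    select_bandwidth,
)


def toy_instance(rng, n=40, p=2, span=1000.0):
    X = rng.standard_normal((n, p))
    coords = rng.uniform(0, span, (n, 2))
    y = X @ rng.standard_normal(p) * 0.3 + 0.5 + rng.standard_normal(n) * 0.1
    return X, y, coords


class TestKernelWeights:
    def test_zero_distance_gives_unit_weight(self, rng):
        coords = rng.uniform(0, 10, (8, 2))
        for kernel in ("gaussian", "bisquare"):
            cfg = GWRConfig(kernel=kernel, bandwidth_mode="fixed_distance", bandwidth=5.0)
            w = kernel_weights(coords[0], coords, cfg)
            assert w[0] == pytest.approx(1.0)
            assert ((w >= 0) & (w <= 1)).all()

    def test_gaussian_closed_form_at_bandwidth_distance(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])  # d = 5
        cfg = GWRConfig(kernel="gaussian", bandwidth_mode="fixed_distance", bandwidth=5.0)
        w = kernel_weights(np.array([0.0, 0.0]), coords, cfg)
        assert w[1] == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_bisquare_closed_form_and_compact_support(self):
        coords = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        cfg = GWRConfig(kernel="bisquare", bandwidth_mode="fixed_distance", bandwidth=10.0)
        w = kernel_weights(np.array([0.0, 0.0]), coords, cfg)
        assert w[1] == pytest.approx(0.5625)  # d = theta/2
        assert w[2] == 0.0 and w[3] == 0.0  # support ends exactly at theta

    def test_adaptive_bandwidth_is_kth_neighbor_distance(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        cfg = GWRConfig(kernel="bisquare", bandwidth_mode="adaptive_neighbors", bandwidth=3)
        w = kernel_weights(coords[0], coords, cfg)
        # theta = distance to 3rd nearest (incl. self) = 2 -> point at d=2 gets 0
        assert w[2] == 0.0 and w[1] > 0

    def test_nonpositive_bandwidth_rejected(self, rng):
        coords = rng.uniform(0, 10, (5, 2))
        cfg = GWRConfig(bandwidth_mode="fixed_distance", bandwidth=-1.0)
        with pytest.raises(ValueError):
            kernel_weights(coords[0], coords, cfg)


class TestFitGWR:
    def test_huge_gaussian_bandwidth_recovers_global_ols(self, rng):
        X, y, coords = toy_instance(rng, n=6)
        cfg = GWRConfig(kernel="gaussian", bandwidth_mode="fixed_distance",
                        bandwidth=1e9)
        model = fit_gwr(X, y, coords, cfg)
        Xd = np.column_stack([np.ones(6), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        assert np.abs(model.coefficients - beta).max() < 1e-6
        assert model.trace_S == pytest.approx(X.shape[1] + 1, abs=1e-6)

    def test_matches_bruteforce_weighted_least_squares(self, rng):
        X, y, coords = toy_instance(rng, n=40)
        cfg = GWRConfig(kernel="bisquare", bandwidth_mode="adaptive_neighbors",
                        bandwidth=15)
        model = fit_gwr(X, y, coords, cfg)
        Xd = np.column_stack([np.ones(len(y)), X])
        for i in range(len(y)):
            w = kernel_weights(coords[i], coords, cfg)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
            assert np.abs(beta - model.coefficients[i]).max() < 1e-8

    def test_dimensional_contracts(self, rng):
        X, y, coords = toy_instance(rng, n=50, p=3)
        cfg = GWRConfig(bandwidth=20)
        model = fit_gwr(X, y, coords, cfg)
        n, q = 50, 4
        assert model.coefficients.shape == (n, q)
        assert q <= model.trace_S <= n
        np.testing.assert_allclose(model.residuals, model.y - model.fitted)
        assert model.local_r2.shape == (n,)

    def test_translation_invariance(self, rng):
        X, y, coords = toy_instance(rng, n=30)
        cfg = GWRConfig(bandwidth=12)
        a = fit_gwr(X, y, coords, cfg)
        b = fit_gwr(X, y, coords + 1000.0, cfg)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)
        np.testing.assert_allclose(a.fitted, b.fitted, atol=1e-9)

    def test_singular_system_with_zero_fallback_raises(self, rng):
        X, y, coords = toy_instance(rng, n=20)
        X = np.column_stack([X[:, 0], X[:, 0]])  # perfectly collinear
        cfg = GWRConfig(bandwidth=10, ridge_fallback=0.0)
        with pytest.raises(np.linalg.LinAlgError):
            fit_gwr(X, y, coords, cfg)


class TestAICc:
    def test_hand_computed_value(self):
        assert aicc_score(1.0, 100, 10.0) == pytest.approx(-151.73, abs=0.01)

    def test_increasing_in_rss(self):
        assert aicc_score(2.0, 100, 10.0) > aicc_score(1.0, 100, 10.0)

    def test_oversmoothing_guard(self):
        with pytest.raises(OversmoothingError):
            aicc_score(1.0, 100, 98.5)


class TestSelectBandwidth:
    def test_golden_section_matches_dense_grid(self, rng):
        X, y, coords = toy_instance(rng, n=120, span=3000.0)
        base = GWRConfig(kernel="bisquare", bandwidth_mode="adaptive_neighbors")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg, profile = select_bandwidth(X, y, coords, base)
            dense = {}
            for k in range(X.shape[1] + 3, 121):
                m = fit_gwr(X, y, coords,
                            GWRConfig(bandwidth=k), compute_diagnostics=False)
                dense[k] = m.aicc
        best_dense = min(dense, key=dense.get)
        assert dense[cfg.bandwidth] <= dense[best_dense] + 0.5

    def test_profile_endpoints_not_below_minimum(self, rng):
        X, y, coords = toy_instance(rng, n=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg, profile = select_bandwidth(X, y, coords, GWRConfig())
        values = dict(profile)
        best = values[cfg.bandwidth]
        lo = min(values)
        hi = max(values)
        assert values[lo] >= best and values[hi] >= best

    def test_invalid_bounds_rejected(self, rng):
        X, y, coords = toy_instance(rng)
        with pytest.raises(ValueError):
            select_bandwidth(X, y, coords, GWRConfig(), bounds=(30, 10))


class TestPredict:
    def test_training_location_prediction_equals_fitted_value(self, rng):
        X, y, coords = toy_instance(rng, n=35)
        cfg = GWRConfig(bandwidth=12)
        model = fit_gwr(X, y, coords, cfg)
        pred = predict_gwr(model, coords[:5], X[:5])
        np.testing.assert_allclose(pred, model.fitted[:5], atol=1e-10)

    def test_infinite_bandwidth_prediction_is_global_ols(self, rng):
        X, y, coords = toy_instance(rng, n=25)
        cfg = GWRConfig(kernel="gaussian", bandwidth_mode="fixed_distance",
                        bandwidth=1e9)
        model = fit_gwr(X, y, coords, cfg)
        new_coords = rng.uniform(0, 1000, (10, 2))
        new_X = rng.standard_normal((10, X.shape[1]))
        pred = predict_gwr(model, new_coords, new_X)
        Xd = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        ref = np.column_stack([np.ones(10), new_X]) @ beta
        np.testing.assert_allclose(pred, ref, atol=1e-6)

    def test_prediction_translation_invariance(self, rng):
        X, y, coords = toy_instance(rng, n=30)
        cfg = GWRConfig(bandwidth=10)
        new_coords = rng.uniform(0, 1000, (7, 2))
        new_X = rng.standard_normal((7, X.shape[1]))
        a = predict_gwr(fit_gwr(X, y, coords, cfg), new_coords, new_X)
        b = predict_gwr(
            fit_gwr(X, y, coords + 500.0, cfg), new_coords + 500.0, new_X
        )
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_out_of_support_point_yields_nodata_with_warning(self, rng):
        X, y, coords = toy_instance(rng, n=20, span=100.0)
        cfg = GWRConfig(kernel="bisquare", bandwidth_mode="fixed_distance",
                        bandwidth=30.0)
        model = fit_gwr(X, y, coords, cfg)
        far = np.array([[1e6, 1e6]])
        with pytest.warns(UserWarning, match="support"):
            pred = predict_gwr(model, far, X[:1])
        assert np.isnan(pred[0])

    def test_design_mismatch_rejected(self, rng):
        X, y, coords = toy_instance(rng, n=20)
        model = fit_gwr(X, y, coords, GWRConfig(bandwidth=8))
        with pytest.raises(ValueError, match="design"):
            predict_gwr(model, coords[:2], X[:2, :1])

    def test_grid_prediction_respects_mask_and_clamp(self, rng):
        X, y, coords = toy_instance(rng, n=60, span=900.0)
        model = fit_gwr(X, y, coords, GWRConfig(bandwidth=20))
        rows = cols = 10
        grids = {f"v{j}": rng.standard_normal((rows, cols)) for j in range(X.shape[1])}
        mask = np.ones((rows, cols), bool)
        mask[0, :] = False
        out = predict_grid(model, grids, list(grids), cell_size=90.0, mask=mask)
        assert np.isnan(out[0]).all()
        valid = out[mask]
        assert np.nanmin(valid) >= 0 and np.nanmax(valid) <= 1
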