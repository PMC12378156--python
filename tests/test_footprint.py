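"""LOOCV metrics, Bayesian optimization and footprint model selection."""

import numpy as np
import pandas as pd
import pytest

from canopyscale.footprint import (
    BOTrialHistory,
    Categorical,
    EvalReport,
    FittedFootprintModel,
    IntRange,
    ModelSpec,
    bo_minimize,
    default_params,
    loocv_evaluate,
    make_estimator,
    mean_absolute_residual,
    prediction_accuracy,
    predict_footprints,
    ratio_r2,
    resid_r2,
    rmse,
    train_and_select,
)


class TestMetrics:
    def test_perfect_predictor_identities(self, rng):
        y = rng.uniform(0.1, 0.9, 30)
        rep = EvalReport.from_predictions(y, y.copy())
        assert rep.r2 == pytest.approx(1.0)
        assert rep.r2_resid == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0)
        assert rep.p_accuracy == pytest.approx(100.0)
        assert rep.mar == pytest.approx(0.0)

    def test_three_point_worked_example(self):
        y = np.array([0.2, 0.5, 0.8])
        yhat = np.array([0.3, 0.5, 0.7])
        assert ratio_r2(y, yhat) == pytest.approx(0.4444, abs=1e-4)
        assert rmse(y, yhat) == pytest.approx(0.08165, abs=1e-5)
        assert prediction_accuracy(y, yhat) == pytest.approx(83.67, abs=0.01)
        assert mean_absolute_residual(y, yhat) == pytest.approx(0.0667, abs=1e-4)

    def test_metrics_invariant_to_row_permutation(self, rng):
        y = rng.uniform(0, 1, 25)
        yhat = y + rng.normal(0, 0.1, 25)
        perm = rng.permutation(25)
        a = EvalReport.from_predictions(y, yhat)
        b = EvalReport.from_predictions(y[perm], yhat[perm])
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_zero_mean_observed_flags_p_undefined(self):
        y = np.array([-1.0, 0.0, 1.0])
        rep = EvalReport.from_predictions(y, y * 0.5)
        assert rep.p_undefined and np.isnan(rep.p_accuracy)

    def test_spread_inflation_raises_ratio_but_lowers_resid_r2(self, rng):
        """Adding pure prediction noise must not look like an improvement
        under the residual-based form (it does under the printed ratio)."""
        y = rng.uniform(0, 1, 200)
        clean = y * 0.7 + 0.15
        noisy = clean + rng.normal(0, 0.3, 200)
        assert ratio_r2(y, noisy) > ratio_r2(y, clean)
        assert resid_r2(y, noisy) < resid_r2(y, clean)


class TestLOOCV:
    def test_mean_predictor_folds_match_hand_computation(self):
        # two-point intuition: leaving out each of (0, 1) predicts the other,
        # so yhat = (1, 0) and RMSE = 1
        assert rmse(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1.0)

        class MeanReg:
            def fit(self, X, y):
                self.m = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self.m)

        y = np.array([0.0, 0.6, 0.9])
        rep = loocv_evaluate(MeanReg, np.zeros((3, 1)), y)
        expected = np.array([(0.6 + 0.9) / 2, (0.0 + 0.9) / 2, (0.0 + 0.6) / 2])
        np.testing.assert_allclose(rep.predictions, expected)

    def test_each_fold_excludes_exactly_its_own_row(self, rng):
        seen = []

        class Probe:
            def fit(self, X, y):
                seen.append(np.sort(X[:, 0]).tolist())
                self.v = 0.5
                return self

            def predict(self, X):
                return np.full(len(X), self.v)

        n = 12
        X = np.arange(n, dtype=float)[:, None]
        y = rng.uniform(0, 1, n)
        loocv_evaluate(Probe, X, y)
        assert len(seen) == n
        for i, train in enumerate(seen):
            assert len(train) == n - 1
            assert float(i) not in train

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loocv_evaluate(ModelSpec.of("knn", {"n_neighbors": 1}),
                           np.zeros((2, 1)), [0.1, 0.2])


class TestBayesianOptimization:
    SPACE = {"x": IntRange(0, 100)}

    @staticmethod
    def quadratic(p):
        return (p["x"] / 100 - 0.3) ** 2

    def test_history_length_equals_budget(self):
        h = bo_minimize(self.quadratic, self.SPACE, n_iter=7, n_init=5, seed=0)
        assert len(h) == 12

    def test_incumbent_trace_is_monotone_nonincreasing(self):
        h = bo_minimize(self.quadratic, self.SPACE, n_iter=15, n_init=5, seed=1)
        trace = h.trace()
        assert (np.diff(trace) <= 0).all()
        assert h.incumbent[1] == trace[-1]

    def test_quadratic_incumbent_near_minimum(self):
        h = bo_minimize(self.quadratic, self.SPACE, n_iter=20, n_init=10, seed=3)
        assert abs(h.incumbent[0]["x"] / 100 - 0.3) <= 0.05

    def test_discrete_space_finds_exact_optimum(self):
        h = bo_minimize(
            lambda p: abs(p["x"] - 4), {"x": IntRange(1, 5)}, n_iter=5, n_init=5, seed=0
        )
        assert h.incumbent[0] == {"x": 4}

    def test_beats_random_search_in_median_over_20_seeds(self):
        margins = []
        for s in range(20):
            h = bo_minimize(self.quadratic, self.SPACE, n_iter=15, n_init=5, seed=s)
            rs_best = min(
                self.quadratic({"x": int(v)})
                for v in np.random.default_rng(s).integers(0, 101, 20)
            )
            margins.append(rs_best - h.incumbent[1])
        assert np.median(margins) >= 0

    def test_non_finite_objective_recorded_as_penalty(self):
        def f(p):
            return float("nan") if p["x"] == 0 else p["x"]

        h = bo_minimize(f, {"x": IntRange(0, 3)}, n_iter=2, n_init=4, seed=0,
                        initial_points=[{"x": 0}, {"x": 2}])
        assert np.isfinite(h.values).all()
        assert h.incumbent[0]["x"] != 0

    def test_budget_below_init_rejected(self):
        with pytest.raises(ValueError):
            bo_minimize(self.quadratic, self.SPACE, n_iter=-1, n_init=5, seed=0)

    def test_categorical_dimension_handled(self):
        def f(p):
            return (p["k"] - 3) ** 2 + (0.0 if p["w"] == "good" else 1.0)

        h = bo_minimize(
            f,
            {"k": IntRange(1, 6), "w": Categorical(("bad", "good"))},
            n_iter=15,
            n_init=8,
            seed=2,
        )
        assert h.incumbent[1] == 0.0

    def test_seeded_determinism(self):
        a = bo_minimize(self.quadratic, self.SPACE, n_iter=10, n_init=5, seed=9)
        b = bo_minimize(self.quadratic, self.SPACE, n_iter=10, n_init=5, seed=9)
        assert a.params == b.params and a.values == b.values


class TestTrainAndSelect:
    @pytest.fixture(scope="class")
    def small_problem(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = np.clip(
            0.5 + 0.2 * X["a"] + rng.normal(0, 0.1, 40), 0, 1
        ).to_numpy()
        return X, y

    def test_single_enabled_learner_is_returned(self, small_problem):
        X, y = small_problem
        res = train_and_select(X, y, budget=10, n_init=5, seed=0, kinds=("knn",))
        assert res.best_kind == "knn"
        assert set(res.reports) == {"knn"}
        assert len(res.histories["knn"]) == 10
        assert {"un-optimized", "optimized"} == set(res.comparison["stage"])

    def test_tuned_rmse_never_above_default(self, small_problem):
        # the default configuration seeds the BO design, so the incumbent
        # objective is at most the default's LOOCV RMSE
        X, y = small_problem
        res = train_and_select(X, y, budget=12, n_init=6, seed=1, kinds=("knn",))
        assert res.reports["knn"].rmse <= res.baseline_reports["knn"].rmse + 1e-12


class TestPredictFootprints:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["f1", "f2"])
        y = rng.uniform(0, 1, 30)
        spec = ModelSpec.of("rfr", {"n_estimators": 20})
        est = make_estimator(spec, seed=0).fit(X.to_numpy(), y)
        return FittedFootprintModel(spec, est, ["f1", "f2"])

    def test_predictions_clamped_and_deterministic(self, fitted, rng):
        table = pd.DataFrame(rng.normal(size=(50, 2)) * 10, columns=["f1", "f2"])
        out1 = predict_footprints(fitted, table)
        out2 = predict_footprints(fitted, table)
        assert out1.predicted_fcc.between(0, 1).all()
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_feature_column_is_named(self, fitted):
        with pytest.raises(KeyError, match="f2"):
            predict_footprints(fitted, pd.DataFrame({"f1": [0.0]}))
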