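"""Splitting arithmetic, linear fits against closed-form oracles, tuned forest."""

import numpy as np
import pandas as pd
import pytest

from ndwti.modeling import (
    DEFAULT_RF_SPACE,
    ModelSpec,
    evaluate,
    fit_mlr,
    fit_rf_tuned,
    fit_simple_regression,
    split_stagewise,
)
from ndwti.tuning import IntUniform


def stage_inputs(n_pre, n_post, rng, p=3):
    return {
        "pre_heading": (
            pd.DataFrame(rng.random((n_pre, p)), columns=[f"f{i}" for i in range(p)]),
            rng.uniform(200, 1600, n_pre),
        ),
        "post_heading": (
            pd.DataFrame(rng.random((n_post, p)), columns=[f"f{i}" for i in range(p)]),
            rng.uniform(600, 1900, n_post),
        ),
    }


class TestSplitStagewise:
    def test_study_sample_counts(self, rng):
        """468 pre-heading -> 351/117 and 234 post-heading -> 176/58 under
        the round-half-up rule; the all-stage sets are their unions."""
        ds = split_stagewise(stage_inputs(468, 234, rng), seed=0)
        assert (ds["pre_heading"].n_train, ds["pre_heading"].n_test) == (351, 117)
        assert (ds["post_heading"].n_train, ds["post_heading"].n_test) == (176, 58)
        assert (ds["all_stage"].n_train, ds["all_stage"].n_test) == (527, 175)

    def test_partitions_disjoint_and_exhaustive(self, rng):
        ds = split_stagewise(stage_inputs(40, 20, rng), seed=3)
        for stage in ("pre_heading", "post_heading"):
            tr = set(map(tuple, ds[stage].X_train.to_numpy()))
            te = set(map(tuple, ds[stage].X_test.to_numpy()))
            assert not tr & te
            assert len(tr) + len(te) == {"pre_heading": 40, "post_heading": 20}[stage]

    def test_same_seed_same_membership(self, rng):
        inputs = stage_inputs(40, 20, rng)
        a = split_stagewise(inputs, seed=9)
        b = split_stagewise(inputs, seed=9)
        pd.testing.assert_frame_equal(a["pre_heading"].X_train, b["pre_heading"].X_train)

    def test_tiny_stage_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 4"):
            split_stagewise(stage_inputs(3, 20, rng), seed=0)


class TestSimpleRegression:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_simple_regression(x, 2 * x + 1)
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.metrics["train"] == pytest.approx((1.0, 0.0), abs=1e-9)

    def test_uninformative_feature_gives_zero_r2(self, rng):
        """A response orthogonal to the feature leaves the fit at the mean
        predictor, whose training R2 is exactly zero."""
        x = rng.random(30)
        y0 = rng.standard_normal(30)
        design = np.column_stack([x, np.ones(30)])
        y = y0 - design @ np.linalg.lstsq(design, y0, rcond=None)[0] + 5.0
        fit = fit_simple_regression(x, y)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.metrics["train"][0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.random(25)
        y = rng.random(25)
        X = np.column_stack([x, np.ones(25)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_simple_regression(x, y)
        assert fit.coefficients[0] == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_simple_regression(np.ones(10), np.arange(10.0))


class TestMlr:
    def test_exact_system_recovered(self, rng):
        X = rng.random((30, 4))
        a = np.array([2.0, -1.0, 0.5, 3.0])
        fit = fit_mlr(X, X @ a + 7.0)
        np.testing.assert_allclose(fit.coefficients, a, atol=1e-8)
        assert fit.intercept == pytest.approx(7.0, abs=1e-8)
        assert fit.metrics["train"][0] == pytest.approx(1.0)

    def test_noise_column_never_hurts_training_r2(self, rng):
        X = rng.random((50, 3))
        y = X[:, 0] * 3 + rng.standard_normal(50)
        r2_small = fit_mlr(X, y).metrics["train"][0]
        X_big = np.column_stack([X, rng.random(50)])
        r2_big = fit_mlr(X_big, y).metrics["train"][0]
        assert r2_big >= r2_small - 1e-12

    def test_matches_lstsq_oracle(self, rng):
        X = rng.random((40, 5))
        y = rng.random(40)
        fit = fit_mlr(X, y)
        design = np.column_stack([X, np.ones(40)])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(
            np.append(fit.coefficients, fit.intercept), oracle, atol=1e-8
        )

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mlr(rng.random((4, 6)), rng.random(4))


class TestEvaluate:
    def test_perfect_prediction(self):
        assert evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (1.0, 0.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = evaluate(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_three_point_worked_example(self):
        r2, rmse = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert r2 == pytest.approx(0.0)
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_truth_sentinel(self):
        r2, rmse = evaluate([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(r2)
        assert rmse == pytest.approx(1.0)

    def test_negative_r2_possible(self):
        r2, _ = evaluate([1.0, 2.0, 3.0], [3.0, 3.0, 0.0])
        assert r2 < 0


def small_spec(seed, n_trials=6):
    space = dict(DEFAULT_RF_SPACE)
    space["n_estimators"] = IntUniform(30, 80)
    return ModelSpec(space=space, n_trials=n_trials, cv_folds=5, seed=seed)


class TestTunedForest:
    def test_seeded_determinism(self, rng):
        X = rng.random((60, 4))
        y = rng.random(60) * 100
        a = fit_rf_tuned(X, y, small_spec(5))
        b = fit_rf_tuned(X, y, small_spec(5))
        assert a.params == b.params
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_predictions_within_training_range(self, rng):
        X = rng.random((60, 4))
        y = rng.uniform(100, 900, 60)
        fit = fit_rf_tuned(X, y, small_spec(2))
        preds = fit.predict(rng.random((30, 4)) * 5 - 2)  # far outside
        assert preds.min() >= y.min() and preds.max() <= y.max()

    def test_tuning_not_worse_than_default_forest(self):
        """On a nonlinear response the tuned forest's held-out R2 is within
        0.02 of (or better than) scikit-learn's default forest, for each of
        five seeds, under the 10-fold CV objective."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.preprocessing import StandardScaler

        margins = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.random((300, 4))
            y = (
                np.sin(4 * X[:, 0]) * 200
                + (X[:, 1] > 0.5) * 150
                + X[:, 2] * 100
                + rng.standard_normal(300) * 30
            )
            Xtr, Xte, ytr, yte = X[:225], X[225:], y[:225], y[225:]
            space = dict(DEFAULT_RF_SPACE)
            space["n_estimators"] = IntUniform(50, 200)
            spec = ModelSpec(space=space, n_trials=20, cv_folds=10, seed=seed)
            tuned = fit_rf_tuned(Xtr, ytr, spec, Xte, yte)
            scaler = StandardScaler().fit(Xtr)
            default = RandomForestRegressor(random_state=seed).fit(
                scaler.transform(Xtr), ytr
            )
            r2_default, _ = evaluate(yte, default.predict(scaler.transform(Xte)))
            margins.append(tuned.metrics["test"][0] - r2_default)
        assert min(margins) >= -0.02

    def test_empty_space_rejected(self, rng):
        spec = ModelSpec(space={}, n_trials=2, cv_folds=3, seed=0)
        with pytest.raises(ValueError):
            fit_rf_tuned(rng.random((20, 3)), rng.random(20), spec)
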