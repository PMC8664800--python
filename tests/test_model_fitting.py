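"""Cross-validated ridge/LASSO/OLS fitting against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from facejudge.evaluation import spearman
from facejudge.model_fitting import (
    FitConfig,
    FittedModel,
    fit_all_attributes,
    fit_attribute_model,
    predict,
)
from facejudge.tables import FeatureTable, RatingTable


def make_tables(X, y_cols, space="toy"):
    ids = [f"f{i:03d}" for i in range(X.shape[0])]
    feats = FeatureTable(space, pd.DataFrame(X, index=ids, columns=[f"x{j}" for j in range(X.shape[1])]))
    ratings = RatingTable(pd.DataFrame(y_cols, index=ids), likert_min=-1e9, likert_max=1e9)
    return feats, ratings


def closed_form_ridge(X, y, lam):
    """Oracle: standardize, center, solve the normal equations directly."""
    mu, sd = X.mean(0), X.std(0)
    Xs = (X - mu) / sd
    yc = y - y.mean()
    p = Xs.shape[1]
    w = np.linalg.solve(Xs.T @ Xs + lam * np.eye(p), Xs.T @ yc)
    return w, y.mean(), mu, sd


class TestRidge:
    def test_fixed_lambda_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        lam = 37.5
        feats, ratings = make_tables(X, {"a": y})
        cfg = FitConfig(method="ridge", lambda_grid=[lam], n_cv_iterations=1, seed=0)
        model = fit_attribute_model(feats, ratings, "a", cfg)
        w_oracle, icpt, _, _ = closed_form_ridge(X, y, lam)
        assert np.allclose(model.weights, w_oracle, atol=1e-8)
        assert model.intercept == pytest.approx(icpt, abs=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.1 * rng.standard_normal(50)
        feats, ratings = make_tables(X, {"a": y})
        small = fit_attribute_model(feats, ratings, "a", FitConfig(lambda_grid=[0.01], n_cv_iterations=1))
        large = fit_attribute_model(feats, ratings, "a", FitConfig(lambda_grid=[1e5], n_cv_iterations=1))
        assert np.abs(large.weights).max() < np.abs(small.weights).max()

    def test_smallest_lambda_approaches_ols(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 4))
        y = X @ np.array([2.0, -1.0, 0.5, 1.5]) + 0.05 * rng.standard_normal(80)
        feats, ratings = make_tables(X, {"a": y})
        ridge = fit_attribute_model(feats, ratings, "a", FitConfig(lambda_grid=[1e-8], n_cv_iterations=1))
        ols = fit_attribute_model(feats, ratings, "a", FitConfig(method="ols", n_cv_iterations=1))
        assert np.allclose(ridge.weights, ols.weights, atol=1e-5)

    def test_selection_reproducible_with_seed(self, small_world):
        feats = small_world.train_features["strong"]
        ratings = small_world.train_ratings
        cfg1 = FitConfig(n_cv_iterations=20, seed=123)
        cfg2 = FitConfig(n_cv_iterations=20, seed=123)
        m1 = fit_all_attributes(feats, ratings, cfg1)
        m2 = fit_all_attributes(feats, ratings, cfg2)
        for a in ratings.attributes:
            assert m1[a].lambda_selected == m2[a].lambda_selected
            assert np.array_equal(m1[a].weights, m2[a].weights)

    def test_ols_degrades_under_multicollinearity_but_ridge_does_not(self):
        rng = np.random.default_rng(3)
        n, p = 60, 40
        z = rng.standard_normal((n, 3))
        X = np.repeat(z, p // 3 + 1, axis=1)[:, :p] + 0.01 * rng.standard_normal((n, p))
        y = z @ np.array([1.0, -1.0, 0.5]) + 0.1 * rng.standard_normal(n)
        Xt = np.repeat(rng.standard_normal((n, 3)), p // 3 + 1, axis=1)[:, :p]
        Xt += 0.01 * rng.standard_normal((n, p))
        feats, ratings = make_tables(X, {"a": y})
        ridge = fit_attribute_model(feats, ratings, "a", FitConfig(n_cv_iterations=30, seed=0))
        ols = fit_attribute_model(feats, ratings, "a", FitConfig(method="ols"))
        # out-of-sample faces generated from the same latent recipe
        zt = rng.standard_normal((n, 3))
        Xtest = np.repeat(zt, p // 3 + 1, axis=1)[:, :p] + 0.01 * rng.standard_normal((n, p))
        ytest = zt @ np.array([1.0, -1.0, 0.5]) + 0.1 * rng.standard_normal(n)
        test_feats = FeatureTable("toy", pd.DataFrame(Xtest, index=[f"t{i}" for i in range(n)], columns=feats.feature_names))
        rho_ridge = spearman(predict(ridge, test_feats), ytest)
        rho_ols = spearman(predict(ols, test_feats), ytest)
        assert rho_ridge > rho_ols


class TestOls:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 3))
        y = 2.0 * X[:, 0] + 1.0
        feats, ratings = make_tables(X, {"a": y})
        model = fit_attribute_model(feats, ratings, "a", FitConfig(method="ols"))
        # weights act on standardized features: w0 = 2 * sd(x0)
        assert model.weights[0] == pytest.approx(2.0 * X[:, 0].std(), abs=1e-8)
        assert np.allclose(model.weights[1:], 0.0, atol=1e-8)
        assert model.intercept == pytest.approx(y.mean(), abs=1e-8)
        fitted = predict(model, feats)
        assert np.allclose(fitted, y, atol=1e-8)


class TestLasso:
    def test_large_penalty_zeroes_all_weights(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        feats, ratings = make_tables(X, {"a": y})
        model = fit_attribute_model(feats, ratings, "a", FitConfig(method="lasso", lambda_grid=[100.0], n_cv_iterations=1))
        assert np.allclose(model.weights, 0.0)

    def test_matches_sklearn_at_fixed_alpha(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 5))
        y = X @ np.array([1.0, 0.0, -0.5, 0.0, 2.0]) + 0.1 * rng.standard_normal(50)
        feats, ratings = make_tables(X, {"a": y})
        model = fit_attribute_model(feats, ratings, "a", FitConfig(method="lasso", lambda_grid=[0.1], n_cv_iterations=1))
        Xs = (X - X.mean(0)) / X.std(0)
        ref = Lasso(alpha=0.1, fit_intercept=False, tol=1e-10, max_iter=50_000).fit(Xs, y - y.mean())
        assert np.allclose(model.weights, ref.coef_, atol=1e-5)


class TestPredict:
    def test_flip_sign_negates_rank_correlation(self, small_world, small_models):
        ts = small_world.test_sets[0]
        attr = small_world.train_ratings.attributes[0]
        feats = ts.features["strong"]
        target = ts.ratings.column(attr)
        rho = spearman(predict(small_models[attr], feats), target)
        rho_flipped = spearman(predict(small_models[attr], feats, flip_sign=True), target)
        assert rho_flipped == pytest.approx(-rho, abs=1e-12)

    def test_space_mismatch_raises(self, small_world, small_models):
        ts = small_world.test_sets[0]
        attr = small_world.train_ratings.attributes[0]
        with pytest.raises(ValueError, match="space mismatch"):
            predict(small_models[attr], ts.features["weak"])

    def test_zero_weights_predict_intercept(self):
        model = FittedModel(
            attribute="a", space_name="toy", weights=np.zeros(2), intercept=3.5,
            lambda_selected=1.0, feature_names=["x0", "x1"],
            mean=np.zeros(2), sd=np.ones(2), method="ridge",
        )
        feats = FeatureTable("toy", pd.DataFrame(np.random.default_rng(0).standard_normal((5, 2)), index=list("abcde"), columns=["x0", "x1"]))
        assert np.allclose(predict(model, feats), 3.5)

    def test_json_round_trip(self, small_models):
        m = next(iter(small_models.values()))
        m2 = FittedModel.from_json(m.to_json())
        assert np.allclose(m.weights, m2.weights)
        assert m.lambda_selected == m2.lambda_selected


class TestFitAllAttributes:
    def test_duplicated_attribute_gets_identical_model(self, small_world):
        ratings = small_world.train_ratings
        dup = RatingTable(
            pd.DataFrame(
                {"a": ratings.ratings.iloc[:, 0], "b": ratings.ratings.iloc[:, 0]},
                index=ratings.ratings.index,
            )
        )
        models = fit_all_attributes(small_world.train_features["strong"], dup, FitConfig(n_cv_iterations=15, seed=3))
        assert models["a"].lambda_selected == models["b"].lambda_selected
        assert np.array_equal(models["a"].weights, models["b"].weights)

    def test_constant_rating_column_rejected(self, small_world):
        bad = RatingTable(
            pd.DataFrame({"flat": 4.0}, index=small_world.train_ratings.ratings.index)
        )
        with pytest.raises(ValueError, match="constant rating"):
            fit_all_attributes(small_world.train_features["strong"], bad, FitConfig(n_cv_iterations=5))

    def test_true_weight_recovery_on_low_noise_world(self):
        from facejudge.synthetic_data import FeatureSpaceSpec, SyntheticWorldConfig, generate_world

        cfg = SyntheticWorldConfig(
            n_latent=3, n_train_faces=500, n_test_faces=20, n_attributes=4,
            rating_noise_sd=0.2, n_raters=30,
            feature_space_specs=[FeatureSpaceSpec("sp", 32, 0.95, 0.0, 0.05, 0.0)],
            seed=11,
        )
        w = generate_world(cfg)
        models = fit_all_attributes(w.train_features["sp"], w.train_ratings, FitConfig(n_cv_iterations=50, seed=1))
        for attr, m in models.items():
            true = w.true_weights["sp"][attr]
            fitted_raw = m.weights / m.sd  # back to raw-feature scale
            assert np.corrcoef(fitted_raw, true)[0, 1] > 0.9
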