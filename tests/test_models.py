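"""Decoder families against closed-form and planted-ground-truth oracles."""

import numpy as np
import pytest

from gripdecode.models import (
    fit_elastic_net,
    fit_gbt,
    fit_mlp,
    fit_wiener,
    r2_score,
    spoc_features,
    spoc_fit,
)


def _design(n, p, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    w = rng.standard_normal(p)
    y = X @ w + noise * rng.standard_normal(n)
    return X, y, w


class TestWiener:
    def test_exact_recovery_matches_pinv_oracle(self):
        X, y, w_true = _design(200, 40, seed=7)
        m = fit_wiener(X, y)
        Xc = X - X.mean(axis=0)
        w_oracle = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.abs(m.coef_ - w_oracle).max() < 1e-6
        assert np.abs(m.coef_ - w_true).max() < 1e-6

    def test_noise_target_no_fit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10_000, 20))
        y = rng.standard_normal(10_000)
        m = fit_wiener(X, y)
        assert r2_score(y, m.predict(X)) < 0.01

    def test_duplicated_column_prediction_unchanged(self):
        X, y, _ = _design(100, 5, seed=2, noise=0.1)
        Xd = np.column_stack([X, X[:, 0]])
        pred = fit_wiener(X, y).predict(X)
        pred_dup = fit_wiener(Xd, y).predict(Xd)
        np.testing.assert_allclose(pred_dup, pred, atol=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_wiener_enet0_pinv_equivalence_property(self, seed):
        X, y, _ = _design(80, 12, seed=seed, noise=0.5)
        w_wiener = fit_wiener(X, y).coef_
        w_enet0 = fit_elastic_net(X, y, alpha=0.0, l1_ratio=0.5).coef_
        w_pinv = np.linalg.pinv(X - X.mean(0)) @ (y - y.mean())
        assert np.abs(w_wiener - w_enet0).max() < 1e-6
        assert np.abs(w_wiener - w_pinv).max() < 1e-6


class TestElasticNet:
    def test_huge_alpha_shrinks_to_intercept(self):
        X, y, _ = _design(100, 8, seed=3, noise=0.2)
        m = fit_elastic_net(X, y, alpha=1e6, l1_ratio=0.5)
        np.testing.assert_allclose(m.coef_, 0.0)
        np.testing.assert_allclose(m.predict(X), y.mean(), rtol=1e-6)

    def test_objective_not_worse_than_ols_point(self):
        X, y, _ = _design(50, 5, seed=4, noise=0.3)
        alpha, rho = 0.1, 0.5

        def objective(w, b):
            resid = X @ w + b - y
            return (
                0.5 * np.mean(resid**2)
                + alpha * rho * np.abs(w).sum()
                + 0.5 * alpha * (1 - rho) * (w**2).sum()
            )

        m = fit_elastic_net(X, y, alpha, rho)
        ols = fit_wiener(X, y)
        assert objective(m.coef_, m.intercept_) <= objective(ols.coef_, ols.intercept_) + 1e-10

    def test_invalid_hyperparameters_rejected(self):
        X, y, _ = _design(30, 3, seed=5)
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, alpha=-1.0, l1_ratio=0.5)
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, alpha=0.5, l1_ratio=1.5)


class TestMLP:
    def test_learns_linear_relation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 1))
        y = 2.0 * X[:, 0] + 0.05 * rng.standard_normal(200)
        m = fit_mlp(X, y, n_layers=1, units=8, learning_rate=5e-3, seed=0)
        assert r2_score(y, m.predict(X)) > 0.8

    def test_shuffled_labels_no_generalization(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2000, 5))
        y = rng.permutation(X @ np.ones(5))
        m = fit_mlp(X[:1600], y[:1600], n_layers=1, units=5, seed=0)
        assert r2_score(y[1600:], m.predict(X[1600:])) <= 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 4))
        y = X @ np.array([1.0, -1, 0.5, 0]) + 0.1 * rng.standard_normal(300)
        p1 = fit_mlp(X, y, seed=7).predict(X)
        p2 = fit_mlp(X, y, seed=7).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_out_of_range_spec_rejected(self):
        with pytest.raises(ValueError):
            fit_mlp(np.zeros((20, 2)), np.zeros(20), n_layers=4)


class TestGBT:
    def test_pure_noise_predicts_mean(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2000, 10))
        y = rng.standard_normal(2000)
        m = fit_gbt(X[:1500], y[:1500], depth=3, eta=0.3, gamma=1.0, seed=0)
        assert r2_score(y[1500:], m.predict(X[1500:])) < 0.05

    def test_step_function_vs_bayes_predictor(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (2000, 3))
        y = np.where(X[:, 0] > 0.0, 1.0, -1.0) + 0.1 * rng.standard_normal(2000)
        m = fit_gbt(X[:1500], y[:1500], depth=2, eta=0.5, gamma=1.0, seed=0)
        assert r2_score(y[1500:], m.predict(X[1500:])) > 0.9

    def test_ten_boosting_rounds_by_default(self):
        X, y, _ = _design(200, 4, seed=5, noise=0.2)
        m = fit_gbt(X, y)
        assert m.n_estimators_ == 10

    def test_training_loss_non_increasing(self):
        X, y, _ = _design(500, 6, seed=6, noise=0.3)
        m = fit_gbt(X, y, depth=3, eta=0.3, gamma=1.0)
        losses = [np.mean((y - p) ** 2) for p in m.staged_predict(X)]
        assert all(b <= a + 1e-12 for a, b in zip(losses[:-1], losses[1:]))


def _planted_spoc(seed=5, E=600, C=6, snr=2.0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(E)
    mix = rng.standard_normal(C)
    src = rng.standard_normal((E, 100)) * np.sqrt(np.exp(0.8 * z))[:, None]
    epochs = mix[None, :, None] * src[:, None, :] + rng.standard_normal((E, C, 100)) / snr
    return epochs, z, mix


class TestSpoc:
    def test_recovers_planted_comodulating_source(self):
        epochs, z, mix = _planted_spoc(seed=5)
        filt = spoc_fit(epochs, z)
        feats = spoc_features(epochs, filt)
        # oracle: features computed with the true mixing vector
        oracle = np.log(np.var(np.einsum("c,ect->et", mix, epochs), axis=1))
        assert abs(np.corrcoef(feats, z)[0, 1]) >= 0.8
        assert abs(np.corrcoef(feats, oracle)[0, 1]) >= 0.8

    def test_null_target_uncorrelated(self):
        # no association can generalize: fit on half, evaluate held-out half
        rng = np.random.default_rng(6)
        epochs = rng.standard_normal((1200, 6, 100))
        z = rng.standard_normal(1200)
        filt = spoc_fit(epochs[:600], z[:600])
        feats = spoc_features(epochs[600:], filt)
        assert abs(np.corrcoef(feats, z[600:])[0, 1]) < 0.1

    def test_scaling_invariance_of_features(self):
        epochs, z, _ = _planted_spoc(seed=7)
        scale = np.array([0.2, 5.0, 1.0, 3.0, 0.5, 2.0])
        scaled = epochs * scale[None, :, None]
        f1 = spoc_features(epochs, spoc_fit(epochs, z))
        f2 = spoc_features(scaled, spoc_fit(scaled, z))
        # log-variance features identical up to an additive constant
        assert np.corrcoef(f1, f2)[0, 1] > 0.999

    def test_single_filter_per_band(self):
        epochs, z, _ = _planted_spoc(seed=8)
        filt = spoc_fit(epochs, z)
        assert filt.w.shape == (6,)
        assert spoc_features(epochs, filt).ndim == 1


class TestR2:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2, 3, 4])
        assert r2_score(y, y) == pytest.approx(1.0)
        assert r2_score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_anticorrelated_raw_and_floored(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(1000)
        y = (y - y.mean()) / y.std()
        assert r2_score(y, -y) == pytest.approx(-3.0, rel=1e-9)
        assert r2_score(y, -y, floor_at_zero=True) == 0.0

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            r2_score(np.ones(10), np.zeros(10))
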