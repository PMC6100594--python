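"""PCA compression and the backpropagation network."""

import numpy as np
import pytest

from gluten_nir.bpann import (
    ANNConfig,
    DivergenceError,
    fit_ann,
    pca_fit,
    pca_transform,
    predict_ann,
    select_pc_count,
    train_bpann,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestPCA:
    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 5))
        basis = pca_fit(X, 5)
        scores = pca_transform(basis, X)
        np.testing.assert_allclose(scores @ basis.loadings.T + basis.x_mean, X, atol=1e-8)

    def test_planted_two_dimensional_subspace(self, rng):
        T = rng.normal(size=(30, 2))
        P = rng.normal(size=(2, 5))
        X = T @ P + rng.normal(1.0, 0.0, size=(30, 5))
        basis = pca_fit(X, 2)
        scores = pca_transform(basis, X)
        np.testing.assert_allclose(scores @ basis.loadings.T + basis.x_mean, X, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        basis = pca_fit(rng.normal(size=(20, 10)), 4)
        np.testing.assert_allclose(basis.loadings.T @ basis.loadings, np.eye(4), atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        """Oracle: covariance eigenvalues of a 6x4 matrix."""
        X = rng.normal(size=(6, 4))
        basis = pca_fit(X, 4)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / 5))[::-1]
        np.testing.assert_allclose(basis.explained_variance_ratio, eig[:4] / eig.sum(), atol=1e-8)
        assert np.all(np.diff(basis.explained_variance_ratio) <= 1e-12)
        assert basis.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(6, 4)), 6)


class TestTraining:
    def test_zero_epochs_returns_seeded_initial_network(self, rng):
        S = rng.normal(size=(12, 3))
        y = rng.uniform(2, 5, 12)
        model = train_bpann(S, y, ANNConfig(epochs=0), seed=5)
        # reproduce the forward pass of the untouched initial weights
        init = np.random.default_rng(5)
        w_in = init.uniform(-0.5, 0.5, size=(3, 5))
        b_in = init.uniform(-0.5, 0.5, size=5)
        w_out = init.uniform(-0.5, 0.5, size=5)
        b_out = float(init.uniform(-0.5, 0.5))
        Ss = (S - S.mean(axis=0)) / S.std(axis=0)
        ys = _sigmoid(Ss @ w_in + b_in) @ w_out + b_out
        expected = y.min() + (ys - 0.1) * (y.max() - y.min()) / 0.8
        np.testing.assert_allclose(predict_ann(model, S), expected, atol=1e-12)

    def test_same_seed_gives_bitwise_identical_weights(self, rng):
        S = rng.normal(size=(20, 4))
        y = S @ np.array([1.0, -0.5, 0.3, 0.2]) + 3.0
        a = train_bpann(S, y, seed=9)
        b = train_bpann(S, y, seed=9)
        assert np.array_equal(a.w_in, b.w_in) and np.array_equal(a.w_out, b.w_out)
        assert a.b_out == b.b_out

    def test_learns_noiseless_linear_target(self, rng):
        S = rng.normal(size=(40, 3))
        y = S @ np.array([1.5, -1.0, 0.5]) + 4.0
        model = train_bpann(S, y, ANNConfig(epochs=2000), seed=2)
        resid = predict_ann(model, S) - y
        assert np.sqrt(np.mean(resid**2)) < 0.05 * y.std()

    def test_divergent_learning_rate_reports_epoch(self, rng):
        S = rng.normal(size=(20, 3)) * 50
        y = rng.uniform(2, 5, 20)
        with pytest.raises(DivergenceError, match="epoch"):
            train_bpann(S, y, ANNConfig(learning_rate=1e4), seed=0)


class TestPredict:
    def test_all_zero_weights_predict_unscaled_output_bias(self, rng):
        S = rng.normal(size=(10, 2))
        y = rng.uniform(1, 5, 10)
        model = train_bpann(S, y, ANNConfig(epochs=0), seed=0)
        model.w_in[:] = 0.0
        model.b_in[:] = 0.0
        model.w_out[:] = 0.0
        model.b_out = 0.5
        expected = y.min() + (0.5 - 0.1) * (y.max() - y.min()) / 0.8
        np.testing.assert_allclose(predict_ann(model, S), expected, atol=1e-12)

    def test_hand_computed_forward_pass(self):
        """2 inputs, 2 hidden units, explicit arithmetic."""
        S = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        model = train_bpann(S, y, ANNConfig(hidden_size=2, epochs=0), seed=1)
        model.w_in = np.array([[0.5, -0.25], [1.0, 0.75]])
        model.b_in = np.array([0.1, -0.2])
        model.w_out = np.array([2.0, -1.0])
        model.b_out = 0.3
        x = np.array([[1.0, 2.0]])
        xs = (x - model.score_mean) / model.score_scale
        h1 = _sigmoid(xs[0, 0] * 0.5 + xs[0, 1] * 1.0 + 0.1)
        h2 = _sigmoid(xs[0, 0] * -0.25 + xs[0, 1] * 0.75 - 0.2)
        ys = 2.0 * h1 - 1.0 * h2 + 0.3
        expected = 0.0 + (ys - 0.1) * 3.0 / 0.8
        np.testing.assert_allclose(predict_ann(model, x), [expected], atol=1e-12)

    def test_training_data_predictions_reproducible(self, rng):
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12) + 5.0
        model = fit_ann(X, y, 3, seed=4)
        a = predict_ann(model, X)
        b = predict_ann(model, X)
        np.testing.assert_array_equal(a, b)

    def test_channel_mismatch_rejected(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.uniform(2, 5, 15)
        model = fit_ann(X, y, 2, seed=0)
        with pytest.raises(ValueError):
            predict_ann(model, rng.normal(size=(3, 5)))


class TestSelectPCCount:
    def test_single_candidate(self, rng):
        X = rng.normal(size=(18, 6))
        y = X[:, 0] * 2 + 3 + rng.normal(0, 0.05, 18)
        best, curve = select_pc_count(X, y, max_pc=1, seed=1)
        assert best == 1 and curve.size == 1

    def test_planted_three_factor_dimension(self, rng):
        """Known latent dimension 3: the RMSECV argmin lands within +-1 of it."""
        n, p = 60, 15
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, p))
        X = T @ P + rng.normal(0, 0.02, size=(n, p))
        y = T @ np.array([2.0, -1.0, 1.5]) + 5.0 + rng.normal(0, 0.05, n)
        cfg = ANNConfig(epochs=800)
        best, _ = select_pc_count(X, y, max_pc=6, config=cfg, seed=3)
        assert abs(best - 3) <= 1
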