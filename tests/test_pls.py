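"""NIPALS PLS1 kernel: oracle equivalences, CV error, component selection."""

import numpy as np
import pytest

from gluten_nir.pls import (
    CVScheme,
    DegenerateTargetError,
    fit_pls,
    predict,
    rmsecv,
    select_n_components,
)


def _ols_predictions(X, y):
    """Independent oracle: centred ordinary least squares via normal equations."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    return Xc @ b + y.mean()


class TestFit:
    def test_single_informative_column_needs_one_component(self, rng):
        # orthogonal centred columns so the first weight vector is exactly e_2
        M = rng.normal(size=(12, 6))
        X, _ = np.linalg.qr(M - M.mean(axis=0))
        y = 3.0 * X[:, 2] + 1.0
        model = fit_pls(X, y, 1)
        assert np.sqrt(np.mean((model.fitted - y) ** 2)) < 1e-10

    def test_full_rank_pls_equals_ols(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model = fit_pls(X, y, 4)
        np.testing.assert_allclose(model.fitted, _ols_predictions(X, y), atol=1e-8)

    def test_full_rank_equivalence_many_instances(self, rng):
        """PLS with as many components as the rank of centred X reproduces OLS."""
        for _ in range(50):
            n, p = int(rng.integers(5, 12)), int(rng.integers(2, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            a = min(n - 1, p)
            np.testing.assert_allclose(fit_pls(X, y, a).fitted, _ols_predictions(X, y), atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 15))
        y = X @ rng.normal(size=15) + rng.normal(0, 0.1, 20)
        T = fit_pls(X, y, 5).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_training_error_non_increasing_in_components(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 25)
        errs = [
            np.sqrt(np.mean((fit_pls(X, y, a).fitted - y) ** 2)) for a in range(1, 9)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DegenerateTargetError):
            fit_pls(rng.normal(size=(6, 3)), np.full(6, 2.0), 1)

    def test_component_bounds_enforced(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError):
            fit_pls(X, y, 4)


class TestPredict:
    def test_training_predictions_reproduced(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(model, X), model.fitted, atol=1e-12)

    def test_mean_row_predicts_mean_target(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(model, X.mean(axis=0)), [model.y_mean], atol=1e-12)

    def test_two_by_two_pencil_and_paper(self):
        """n=2, p=2: one NIPALS component worked by hand gives b=[0.5, 0.5]."""
        X = np.array([[0.0, 1.0], [2.0, 3.0]])
        y = np.array([1.0, 3.0])
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(model.coef, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(predict(model, [[0.0, 1.0]]), [1.0], atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        model = fit_pls(rng.normal(size=(8, 4)), rng.normal(size=8), 2)
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(3, 5)))

    def test_consistent_channel_reordering_is_invariant(self, rng):
        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.1, 15)
        Xt = rng.normal(size=(4, 8))
        perm = rng.permutation(8)
        a = predict(fit_pls(X, y, 3), Xt)
        b = predict(fit_pls(X[:, perm], y, 3), Xt[:, perm])
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestRMSECV:
    def test_noiseless_linear_data(self, rng):
        X = rng.normal(size=(15, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 5.0
        assert rmsecv(X, y, 4) < 1e-6

    def test_loo_matches_hand_enumerated_univariate_oracle(self):
        """n=4, one variable: four explicit held-out univariate regressions."""
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        sq = 0.0
        for i in range(4):
            tr = [j for j in range(4) if j != i]
            xt, yt = x[tr], y[tr]
            slope = np.sum((xt - xt.mean()) * (yt - yt.mean())) / np.sum((xt - xt.mean()) ** 2)
            pred = yt.mean() + slope * (x[i] - xt.mean())
            sq += (pred - y[i]) ** 2
        oracle = np.sqrt(sq / 4)
        got = rmsecv(x[:, None], y, 1, CVScheme(kind="loo"))
        np.testing.assert_allclose(got, oracle, atol=1e-12)

    def test_kfold_contiguous_folds_partition(self):
        folds = CVScheme(kind="kfold", k=3).folds(10)
        assert [len(f) for f in folds] == [4, 3, 3]
        assert sorted(np.concatenate(folds)) == list(range(10))


class TestSelectComponents:
    def test_single_candidate(self, rng):
        X = rng.normal(size=(10, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 10)
        best, curve = select_n_components(X, y, max_pc=1)
        assert best == 1 and curve.size == 1

    def test_recovers_intrinsic_dimension_three(self, rng):
        """Three latent factors with low noise: the RMSECV minimum sits at 3."""
        n, p = 40, 20
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, p))
        X = T @ P + rng.normal(0, 0.01, size=(n, p))
        y = T @ np.array([1.0, -1.5, 2.0]) + rng.normal(0, 0.01, n)
        best, _ = select_n_components(X, y, max_pc=8)
        assert best == 3

    def test_curve_minimum_is_selected(self, rng):
        X = rng.normal(size=(20, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.3, 20)
        best, curve = select_n_components(X, y, max_pc=6)
        assert curve[best - 1] == curve.min()
        assert best - 1 == int(np.argmin(curve))
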