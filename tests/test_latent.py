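"""PCA and PLS: decomposition identities, oracles and PRESS selection."""

import numpy as np
import pytest

from leafspec import (
    pca_fit,
    pca_transform,
    pls_fit,
    pls_predict,
    pls_scores,
    select_lvs_by_press,
)


def random_low_rank(rng, n, k, rank, noise=0.0):
    X = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, k))
    if noise:
        X = X + noise * rng.standard_normal((n, k))
    return X


class TestPCA:
    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X = random_low_rank(rng, 25, 40, rank=8, noise=0.1)
        model = pca_fit(X, 6)
        P = model.loadings
        assert np.allclose(P.T @ P, np.eye(6), atol=1e-10)
        recon = model.scores @ P.T + model.mean_spectrum
        err6 = np.linalg.norm(X - recon)
        model8 = pca_fit(X, 8)
        recon8 = model8.scores @ model8.loadings.T + model8.mean_spectrum
        assert np.linalg.norm(X - recon8) <= err6  # error non-increasing in A

    def test_rank_one_data_explained_by_first_component(self, rng):
        pattern = rng.standard_normal(30)
        amps = rng.standard_normal(12)
        X = np.outer(amps, pattern)
        model = pca_fit(X, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_rank6_data_cumulative_variance(self, rng):
        X = random_low_rank(rng, 30, 50, rank=6)
        model = pca_fit(X, 6)
        assert model.explained_variance_fraction.sum() >= 0.999
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_transform_self_consistency(self, rng):
        X = random_low_rank(rng, 20, 30, rank=5, noise=0.05)
        model = pca_fit(X, 4)
        assert np.allclose(pca_transform(model, X), model.scores, atol=1e-10)

    def test_transform_mean_is_zero_and_loading_is_unit_score(self, rng):
        X = random_low_rank(rng, 20, 30, rank=5, noise=0.05)
        model = pca_fit(X, 4)
        assert np.allclose(pca_transform(model, model.mean_spectrum), 0.0, atol=1e-10)
        shifted = model.mean_spectrum + model.loadings[:, 0]
        expected = np.zeros(4)
        expected[0] = 1.0
        assert np.allclose(pca_transform(model, shifted), expected, atol=1e-10)

    def test_sign_convention_fixed(self, rng):
        X = random_low_rank(rng, 20, 30, rank=5, noise=0.05)
        model = pca_fit(X, 4)
        P = model.loadings
        picks = P[np.argmax(np.abs(P), axis=0), np.arange(4)]
        assert np.all(picks > 0)

    def test_too_many_components_rejected(self, rng):
        X = rng.standard_normal((10, 30))
        with pytest.raises(ValueError):
            pca_fit(X, 10)  # limit is N-1 = 9

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = random_low_rank(rng, 25, 40, rank=8, noise=0.1)
        model = pca_fit(X, 5)
        ref = sklearn.PCA(n_components=5).fit(X)
        # compare up to the sign convention
        for a in range(5):
            dot = abs(float(ref.components_[a] @ model.loadings[:, a]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, atol=1e-10
        )


class TestPLS:
    def test_single_factor_noiseless_needs_one_lv(self, rng):
        k = 30
        direction = rng.standard_normal(k)
        t = rng.standard_normal(40)
        X = np.outer(t, direction)
        y = 3.0 * t + 1.0
        model = pls_fit(X, y, 1)
        assert np.max(np.abs(pls_predict(model, X) - y)) < 1e-8

    def test_max_lvs_equals_ols_on_full_rank_data(self, rng):
        n, k = 25, 10
        X = rng.standard_normal((n, k))
        y = rng.standard_normal(n)
        model = pls_fit(X, y, max_lvs=k)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = y.mean() + Xc @ beta
        assert np.allclose(pls_predict(model, X), ols_pred, atol=1e-6)

    def test_regression_vector_reproduces_training_predictions(self, rng):
        X = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        model = pls_fit(X, y, 5)
        via_vector = model.y_mean + (X - model.x_mean) @ model.regression_vector
        assert np.allclose(via_vector, pls_predict(model, X), atol=1e-8)

    def test_one_lv_is_covariance_direction(self, rng):
        """The first PLS weight is the normalized covariance Xᵀy direction."""
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        model = pls_fit(X, y, 1)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        assert abs(abs(w @ model.weights[:, 0]) - 1.0) < 1e-10

    def test_zero_lvs_predicts_mean(self, rng):
        X = rng.standard_normal((20, 15))
        y = rng.standard_normal(20)
        model = pls_fit(X, y, 3)
        assert np.allclose(pls_predict(model, X, n_lvs=0), y.mean(), atol=1e-12)

    def test_constant_response_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            pls_fit(X, np.full(10, 3.0), 2)

    def test_scores_self_consistency_and_mean_zero(self, rng):
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        model = pls_fit(X, y, 4)
        assert np.allclose(pls_scores(model, X), model.scores, atol=1e-10)
        assert np.allclose(pls_scores(model, model.x_mean), 0.0, atol=1e-10)

    def test_predictions_match_sklearn(self, rng):
        pls_ref = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((40, 25))
        y = rng.standard_normal(40)
        model = pls_fit(X, y, 5)
        ref = pls_ref.PLSRegression(n_components=5, scale=False).fit(X, y)
        assert np.allclose(
            pls_predict(model, X), ref.predict(X).ravel(), atol=1e-6
        )
        # scores agree up to component sign
        T_ref = ref.transform(X)
        for a in range(5):
            r = np.corrcoef(T_ref[:, a], model.scores[:, a])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-6

    def test_sample_order_invariance(self, rng):
        X = rng.standard_normal((25, 30))
        y = rng.standard_normal(25)
        perm = rng.permutation(25)
        m1 = pls_fit(X, y, 4)
        m2 = pls_fit(X[perm], y[perm], 4)
        probe = rng.standard_normal((5, 30))
        assert np.allclose(pls_predict(m1, probe), pls_predict(m2, probe), atol=1e-8)


class TestPressSelection:
    def test_press_curve_matches_explicit_loo_loop(self, rng):
        n, k, max_lvs = 10, 6, 3
        X = rng.standard_normal((n, k))
        y = rng.standard_normal(n)
        n_sel, curve = select_lvs_by_press(X, y, max_lvs)
        oracle = np.zeros(max_lvs)
        for i in range(n):
            keep = np.arange(n) != i
            m = pls_fit(X[keep], y[keep], max_lvs)
            for a in range(1, max_lvs + 1):
                pred = pls_predict(m, X[i : i + 1], n_lvs=a)[0]
                oracle[a - 1] += (pred - y[i]) ** 2
        assert np.allclose(curve, oracle, atol=1e-10)
        assert curve[n_sel - 1] == curve.min()

    def test_selected_count_is_argmin(self, rng):
        X = rng.standard_normal((15, 10))
        y = rng.standard_normal(15)
        n_sel, curve = select_lvs_by_press(X, y, 5)
        assert np.all(curve[n_sel - 1] <= curve)

    def test_recovers_known_latent_rank(self):
        """Rank-3 signal + 5% noise: LOO-PRESS picks 3 LVs in most replicates."""
        hits = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n, k = 40, 60
            T = rng.standard_normal((n, 3))
            P = rng.standard_normal((3, k))
            beta = np.array([2.0, -1.0, 0.5])
            signal = T @ beta
            X = T @ P + 0.05 * rng.standard_normal((n, k))
            y = signal + 0.05 * np.std(signal) * rng.standard_normal(n)
            n_sel, _ = select_lvs_by_press(X, y, 8)
            hits += n_sel == 3
        assert hits >= 8
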