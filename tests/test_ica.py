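"""FastICA source recovery, whitening, determinism and SW selection."""

import numpy as np
import pytest

from leafspec import (
    SpectraSet,
    SyntheticConfig,
    extract_sw_features,
    fastica_fit,
    generate_dataset,
    select_sensitive_wavelengths,
)
from leafspec.ica import ICAConvergenceWarning


def mixed_sources(rng, n_obs=50, k=2000):
    """Two independent non-Gaussian sources under a random mixing matrix."""
    s1 = rng.uniform(-np.sqrt(3), np.sqrt(3), k)
    s2 = rng.laplace(0.0, 1 / np.sqrt(2), k)
    S = np.vstack([s1, s2])
    A = rng.standard_normal((n_obs, 2))
    return A @ S, S


def matched_correlations(S_true, S_est):
    """Best |correlation| per true source over estimated components."""
    c = np.abs(np.corrcoef(S_true, S_est)[: S_true.shape[0], S_true.shape[0]:])
    out = []
    used = set()
    for i in range(S_true.shape[0]):
        j = int(np.argmax([c[i, j] if j not in used else -1 for j in range(c.shape[1])]))
        used.add(j)
        out.append(c[i, j])
    return np.array(out)


class TestFastICA:
    def test_recovers_two_sources(self, rng):
        X, S = mixed_sources(rng)
        model = fastica_fit(X, n_components=2, seed=0)
        corr = matched_correlations(S, model.sources)
        assert np.all(corr >= 0.99)

    def test_whitened_intermediate_identity_covariance(self, rng):
        X, _ = mixed_sources(rng)
        model = fastica_fit(X, n_components=2, seed=0)
        Xc = X - model.data_mean[:, None]
        Z = model.whitening @ Xc
        assert np.allclose(Z @ Z.T / Z.shape[1], np.eye(2), atol=1e-8)

    def test_sources_zero_mean_unit_variance_uncorrelated(self, rng):
        X, _ = mixed_sources(rng)
        model = fastica_fit(X, n_components=2, seed=0)
        S = model.sources
        assert np.allclose(S.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(S.var(axis=1), 1.0, atol=1e-6)
        assert abs(np.corrcoef(S)[0, 1]) <= 0.1

    def test_reconstruction_from_mixing(self, rng):
        X, _ = mixed_sources(rng)
        model = fastica_fit(X, n_components=2, seed=0)
        Xc = X - model.data_mean[:, None]
        rel_err = np.linalg.norm(Xc - model.mixing @ model.sources) / np.linalg.norm(Xc)
        assert rel_err <= 0.05

    def test_same_seed_identical_model(self, rng):
        X, _ = mixed_sources(rng)
        m1 = fastica_fit(X, n_components=2, seed=5)
        m2 = fastica_fit(X, n_components=2, seed=5)
        assert np.array_equal(m1.sources, m2.sources)
        assert np.array_equal(m1.mixing, m2.mixing)

    def test_different_seed_same_sources_up_to_permutation_sign(self, rng):
        X, _ = mixed_sources(rng)
        m1 = fastica_fit(X, n_components=2, seed=1)
        m2 = fastica_fit(X, n_components=2, seed=2)
        corr = matched_correlations(m1.sources, m2.sources)
        assert np.all(corr >= 0.99)

    def test_gaussian_sources_flag_nonconvergence_or_weak_structure(self, rng):
        X = rng.standard_normal((30, 1500))
        with pytest.warns(ICAConvergenceWarning):
            # pure Gaussian data is unidentifiable; tight tolerance forces the
            # iteration to its cap
            model = fastica_fit(X, n_components=3, seed=0, tol=1e-12, max_iter=25)
        assert not model.converged

    def test_components_ordered_by_explained_variance(self, rng):
        X, _ = mixed_sources(rng)
        model = fastica_fit(X, n_components=2, seed=0)
        assert model.explained_variance[0] >= model.explained_variance[1]

    def test_too_many_components_rejected(self, rng):
        X = rng.standard_normal((5, 100))
        with pytest.raises(ValueError):
            fastica_fit(X, n_components=6)

    def test_separation_improves_with_sample_size(self):
        """Amari-style unmixing error shrinks as the number of points grows."""

        def amari_error(n_points, seed):
            rng = np.random.default_rng(seed)
            X, S = mixed_sources(rng, n_obs=8, k=n_points)
            model = fastica_fit(X, n_components=2, seed=0)
            c = np.abs(np.corrcoef(S, model.sources)[:2, 2:])
            # 1 - mean matched correlation as a permutation-free error proxy
            return 1.0 - matched_correlations(S, model.sources).mean()

        errs_small = np.median([amari_error(50, s) for s in range(5)])
        errs_large = np.median([amari_error(500, s) for s in range(5)])
        assert errs_large <= errs_small


class TestSensitiveWavelengths:
    def test_lone_gaussian_bump_selects_its_argmax(self):
        wl = 400.0 + np.arange(601.0)
        bump = np.exp(-0.5 * ((wl - 700.0) / 15.0) ** 2)
        model_stub = _StubICA(sources=np.atleast_2d(bump))
        sws = select_sensitive_wavelengths(model_stub, wl, n_sws=1, n_ics_used=1)
        assert sws.wavelengths_nm[0] == 700.0

    def test_band_centers_localized_on_synthetic_spectra(self):
        """True bands at 560/680/960 nm are each near a selected SW."""
        hits = 0
        reps = 10
        for seed in range(reps):
            data = generate_dataset(SyntheticConfig(seed=seed))
            model = fastica_fit(data.reflectance, n_components=4, seed=seed)
            sws = select_sensitive_wavelengths(model, data.wavelengths_nm)
            ok = all(
                np.min(np.abs(sws.wavelengths_nm - center)) <= 12.0
                for center in (560.0, 680.0, 960.0)
            )
            hits += ok
        assert hits >= 8

    def test_minimum_separation_enforced(self, default_dataset):
        model = fastica_fit(default_dataset.reflectance, n_components=4, seed=0)
        sws = select_sensitive_wavelengths(
            model, default_dataset.wavelengths_nm, n_sws=6, min_separation_nm=10.0
        )
        w = np.sort(sws.wavelengths_nm)
        assert np.all(np.diff(w) >= 10.0)

    def test_each_used_component_contributes_when_feasible(self, default_dataset):
        model = fastica_fit(default_dataset.reflectance, n_components=4, seed=1)
        sws = select_sensitive_wavelengths(model, default_dataset.wavelengths_nm)
        assert set(sws.source_component_index) == {0, 1, 2, 3}

    def test_scale_invariance_of_selection(self, default_dataset):
        X = default_dataset.reflectance
        m1 = fastica_fit(X, n_components=4, seed=3)
        m2 = fastica_fit(7.5 * X, n_components=4, seed=3)
        s1 = select_sensitive_wavelengths(m1, default_dataset.wavelengths_nm)
        s2 = select_sensitive_wavelengths(m2, default_dataset.wavelengths_nm)
        assert np.array_equal(np.sort(s1.wavelengths_nm), np.sort(s2.wavelengths_nm))

    def test_selection_deterministic_given_model(self, default_dataset):
        model = fastica_fit(default_dataset.reflectance, n_components=4, seed=2)
        s1 = select_sensitive_wavelengths(model, default_dataset.wavelengths_nm)
        s2 = select_sensitive_wavelengths(model, default_dataset.wavelengths_nm)
        assert np.array_equal(s1.wavelengths_nm, s2.wavelengths_nm)


class TestExtractFeatures:
    def test_feature_matrix_shape_and_values(self, default_dataset):
        model = fastica_fit(default_dataset.reflectance, n_components=4, seed=0)
        sws = select_sensitive_wavelengths(model, default_dataset.wavelengths_nm)
        F = extract_sw_features(default_dataset, sws)
        assert F.shape == (90, 6)
        for j, wl in enumerate(sws.wavelengths_nm):
            col = int(np.argmin(np.abs(default_dataset.wavelengths_nm - wl)))
            assert np.array_equal(F[:, j], default_dataset.reflectance[:, col])

    def test_off_grid_wavelength_rejected(self, default_dataset):
        stub = _StubSWs(np.array([560.5]))
        with pytest.raises(ValueError, match="not on the data grid"):
            extract_sw_features(default_dataset, stub)


class _StubICA:
    def __init__(self, sources):
        self.sources = sources
        self.n_components = sources.shape[0]


class _StubSWs:
    def __init__(self, wavelengths_nm):
        self.wavelengths_nm = wavelengths_nm
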