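"""Latent-variable models: PCA and univariate PLS with PRESS-based selection.

PCA decomposes the mean-centred spectra matrix X (N samples × K wavelengths)
as X = T Pᵀ + E with orthonormal loadings P and scores T, computed by SVD.
PLS1 is fitted by classical NIPALS deflation for a single response (the
element concentration); the optimal number of latent variables is chosen by
leave-one-out cross-validation, minimising the predicted residual error sum of
squares PRESS(a) = Σᵢ (ŷ₋ᵢ(a) − yᵢ)² over LV counts a, with the smallest a
winning ties. Sign indeterminacy in both decompositions is resolved by making
the largest-magnitude loading (PCA) or weight (PLS) element of each component
positive, so fits are reproducible across BLAS builds and sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAModel",
    "PLSModel",
    "pca_fit",
    "pca_transform",
    "pls_fit",
    "pls_predict",
    "pls_scores",
    "select_lvs_by_press",
]


@dataclass(frozen=True)
class PCAModel:
    mean_spectrum: np.ndarray      # (K,)
    loadings: np.ndarray           # (K, A), orthonormal columns
    scores: np.ndarray             # (N, A)
    explained_variance_fraction: np.ndarray  # (A,)
    n_components: int


@dataclass(frozen=True)
class PLSModel:
    n_lvs: int
    x_mean: np.ndarray             # (K,)
    y_mean: float
    weights: np.ndarray            # (K, A) NIPALS weight vectors w_a (unit norm)
    x_loadings: np.ndarray         # (K, A) p_a
    y_loadings: np.ndarray         # (A,)   q_a
    scores: np.ndarray             # (N, A) training scores t_a
    regression_vector: np.ndarray  # (K,) for n_lvs components
    press_curve: np.ndarray | None = None  # (max_lvs,) indexed by LV count 1..max


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    """Mean-centred PCA by singular value decomposition.

    Explained-variance fractions are relative to the total variance of the
    centred matrix; component signs follow the largest-loading-positive rule.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    max_comp = min(n - 1, k)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    P = Vt[:n_components].T
    T = U[:, :n_components] * s[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    P = P * flip
    T = T * flip
    evf = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAModel(mean, P, T, evf, n_components)


def pca_transform(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra onto the fitted loadings: (X − mean)·P."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.mean_spectrum.size:
        raise ValueError(
            f"expected {model.mean_spectrum.size} wavelengths, got {X_new.shape[1]}"
        )
    return (X_new - model.mean_spectrum) @ model.loadings


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lvs: int):
    """Classical NIPALS deflation for a single response; returns W, P, q, T."""
    n, k = Xc.shape
    W = np.zeros((k, n_lvs))
    P = np.zeros((k, n_lvs))
    q = np.zeros(n_lvs)
    T = np.zeros((n, n_lvs))
    X_work = Xc.copy()
    y_work = yc.copy()
    for a in range(n_lvs):
        w = X_work.T @ y_work
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # X no longer covaries with y: keep remaining components at zero
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        w /= norm
        flip = np.sign(w[np.argmax(np.abs(w))]) or 1.0
        w *= flip
        t = X_work @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        p = X_work.T @ t / tt
        qa = float(y_work @ t) / tt
        X_work -= np.outer(t, p)
        y_work = y_work - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    return W, P, q, T


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def pls_fit(X: np.ndarray, y: np.ndarray, max_lvs: int, press_curve: np.ndarray | None = None) -> PLSModel:
    """Fit univariate PLS with ``max_lvs`` components on centred data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n < 3:
        raise ValueError("PLS requires at least 3 samples")
    if y.size != n:
        raise ValueError("y length must match number of samples")
    if not 1 <= max_lvs <= min(n - 1, k):
        raise ValueError(f"max_lvs must be in [1, {min(n - 1, k)}], got {max_lvs}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance; PLS undefined for constant response")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_pls1(X - x_mean, y - y_mean, max_lvs)
    b = _regression_vector(W, P, q)
    return PLSModel(
        n_lvs=W.shape[1], x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        regression_vector=b, press_curve=press_curve,
    )


def pls_scores(model: PLSModel, X_new: np.ndarray, n_lvs: int | None = None) -> np.ndarray:
    """PLS score projection of new spectra via the deflation-weight recursion."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} wavelengths, got {X_new.shape[1]}"
        )
    a_max = model.n_lvs if n_lvs is None else n_lvs
    if not 0 <= a_max <= model.n_lvs:
        raise ValueError(f"n_lvs must be in [0, {model.n_lvs}]")
    Xc = X_new - model.x_mean
    T = np.zeros((X_new.shape[0], a_max))
    for a in range(a_max):
        t = Xc @ model.weights[:, a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
        T[:, a] = t
    return T


def pls_predict(model: PLSModel, X_new: np.ndarray, n_lvs: int | None = None) -> np.ndarray:
    """Predict the response; 0 LVs returns the calibration mean for every input."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    a = model.n_lvs if n_lvs is None else n_lvs
    if a == model.n_lvs:
        b = model.regression_vector
    else:
        if not 0 <= a <= model.n_lvs:
            raise ValueError(f"n_lvs must be in [0, {model.n_lvs}]")
        b = _regression_vector(model.weights[:, :a], model.x_loadings[:, :a], model.y_loadings[:a])
    return model.y_mean + (X_new - model.x_mean) @ b


def select_lvs_by_press(
    X: np.ndarray, y: np.ndarray, max_lvs: int
) -> tuple[int, np.ndarray]:
    """Choose the LV count by leave-one-out PRESS.

    Returns ``(n_lvs, press_curve)`` with ``press_curve[a-1]`` the PRESS for a
    components; the arg-min (smallest count on ties) is selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not 1 <= max_lvs <= min(n - 2, X.shape[1]):
        raise ValueError(
            f"max_lvs must be in [1, {min(n - 2, X.shape[1])}] for leave-one-out"
        )
    press = np.zeros(max_lvs)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = pls_fit(X[keep], y[keep], max_lvs)
        for a in range(1, max_lvs + 1):
            pred = pls_predict(model, X[i : i + 1], n_lvs=min(a, model.n_lvs))[0]
            press[a - 1] += (pred - y[i]) ** 2
    n_lvs = int(np.argmin(press)) + 1  # argmin returns the first (smallest) index on ties
    return n_lvs, press
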