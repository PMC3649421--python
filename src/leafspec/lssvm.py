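"""Least-squares support vector machine regression with RBF kernel.

LS-SVM replaces the quadratic program of the classical SVM by one symmetric
linear system. With kernel matrix Ω (Ωᵢⱼ = K(xᵢ, xⱼ)), regularisation γ and
targets y, the support values α and bias b solve

    [ 0   1ᵀ          ] [ b ]   [ 0 ]
    [ 1   Ω + I/γ     ] [ α ] = [ y ]

and the predictor is y(x) = Σₖ αₖ K(x, xₖ) + b. The RBF kernel follows the
convention K(u, v) = exp(−‖u−v‖² / σ²) (no factor 2), matching the customary
``sig2`` parameterisation. Features are standardised by calibration statistics
before kerneling because σ² is shared across feature columns of very different
scales (e.g. PC scores next to raw reflectances).

Hyperparameters (γ, σ²) are tuned by a two-stage grid search minimising the
root-mean-square error of cross-validation (RMSECV): a crude pass on an
integer log₂ grid over γ ∈ [2⁻¹, 2¹⁰] and σ² ∈ [2¹, 2¹⁵], then a refined pass
at log₂ step 0.25 within one crude step of the crude optimum. Fold assignment
is seeded once and shared across all grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

__all__ = [
    "LSSVMModel",
    "GridSearchResult",
    "rbf_kernel",
    "linear_kernel",
    "lssvm_fit",
    "lssvm_predict",
    "grid_search",
]

DEFAULT_GAMMA_LOG2_RANGE = (-1.0, 10.0)
DEFAULT_SIGMA2_LOG2_RANGE = (1.0, 15.0)


@dataclass(frozen=True)
class LSSVMModel:
    training_inputs: np.ndarray   # (N, d) standardised features
    support_values: np.ndarray    # (N,) α
    bias: float                   # b
    gamma: float
    sigma2: float                 # ignored for the linear kernel
    feature_center: np.ndarray    # (d,)
    feature_scale: np.ndarray     # (d,)
    kernel: str = "rbf"


@dataclass(frozen=True)
class GridSearchResult:
    crude_grid: list[tuple[float, float, float]]    # (log2 γ, log2 σ², RMSECV)
    refined_grid: list[tuple[float, float, float]]
    best_gamma: float
    best_sigma2: float
    best_rmsecv: float


def rbf_kernel(U: np.ndarray, V: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian kernel matrix K(i,j) = exp(−‖uᵢ−vⱼ‖²/σ²)."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    U, V = np.atleast_2d(U), np.atleast_2d(V)
    if U.shape[1] != V.shape[1]:
        raise ValueError("feature dimensions differ")
    return np.exp(-cdist(U, V, "sqeuclidean") / sigma2)


def linear_kernel(U: np.ndarray, V: np.ndarray, sigma2: float | None = None) -> np.ndarray:
    """Inner-product kernel, provided for closed-form cross-checks."""
    U, V = np.atleast_2d(U), np.atleast_2d(V)
    if U.shape[1] != V.shape[1]:
        raise ValueError("feature dimensions differ")
    return U @ V.T


_KERNELS = {"rbf": rbf_kernel, "linear": linear_kernel}


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return center, scale


def lssvm_fit(
    X_features: np.ndarray,
    y: np.ndarray,
    gamma: float,
    sigma2: float = 1.0,
    kernel: str = "rbf",
) -> LSSVMModel:
    """Solve the LS-SVM dual system on calibration-standardised features."""
    X = np.atleast_2d(np.asarray(X_features, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise ValueError("LS-SVM requires at least 2 samples")
    if y.size != n:
        raise ValueError("y length must match number of rows")
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    center, scale = _standardize_stats(X)
    Z = (X - center) / scale
    K = _KERNELS[kernel](Z, Z, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    sol = solve(A, rhs, assume_a="sym")
    residual = float(np.max(np.abs(A @ sol - rhs)))
    if residual > 1e-6:
        raise np.linalg.LinAlgError(
            f"LS-SVM system solved with residual {residual:.2e} > 1e-6"
        )
    return LSSVMModel(
        training_inputs=Z, support_values=sol[1:], bias=float(sol[0]),
        gamma=float(gamma), sigma2=float(sigma2),
        feature_center=center, feature_scale=scale, kernel=kernel,
    )


def lssvm_predict(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Evaluate y(x) = Σ αₖ K(x, xₖ) + b on new feature rows."""
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.training_inputs.shape[1]:
        raise ValueError(
            f"expected {model.training_inputs.shape[1]} features, got {X.shape[1]}"
        )
    Z = (X - model.feature_center) / model.feature_scale
    K = _KERNELS[model.kernel](Z, model.training_inputs, model.sigma2)
    return K @ model.support_values + model.bias


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = np.array_split(perm, folds)
    for part in parts:
        if part.size < 2:
            raise ValueError(
                f"{folds}-fold split of {n} samples leaves a fold with <2 samples"
            )
    return parts


def _rmsecv(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float,
    fold_parts: list[np.ndarray], kernel: str,
) -> float:
    n = X.shape[0]
    sq_err = 0.0
    idx = np.arange(n)
    for held in fold_parts:
        train = np.setdiff1d(idx, held, assume_unique=False)
        model = lssvm_fit(X[train], y[train], gamma=gamma, sigma2=sigma2, kernel=kernel)
        pred = lssvm_predict(model, X[held])
        sq_err += float(np.sum((pred - y[held]) ** 2))
    return float(np.sqrt(sq_err / n))


def grid_search(
    X_features: np.ndarray,
    y: np.ndarray,
    gamma_log2_range: tuple[float, float] = DEFAULT_GAMMA_LOG2_RANGE,
    sigma2_log2_range: tuple[float, float] = DEFAULT_SIGMA2_LOG2_RANGE,
    folds: int = 10,
    seed: int = 0,
    crude_step: float = 1.0,
    refine_step: float = 0.25,
    kernel: str = "rbf",
) -> GridSearchResult:
    """Two-stage (crude then refined) RMSECV minimisation over (γ, σ²)."""
    X = np.atleast_2d(np.asarray(X_features, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    g_lo, g_hi = gamma_log2_range
    s_lo, s_hi = sigma2_log2_range
    if g_lo > g_hi or s_lo > s_hi:
        raise ValueError("invalid log2 search ranges")
    fold_parts = _fold_indices(X.shape[0], folds, seed)

    def sweep(g_vals: np.ndarray, s_vals: np.ndarray) -> list[tuple[float, float, float]]:
        out = []
        for lg in g_vals:
            for ls in s_vals:
                r = _rmsecv(X, y, 2.0**lg, 2.0**ls, fold_parts, kernel)
                out.append((float(lg), float(ls), r))
        return out

    crude = sweep(np.arange(g_lo, g_hi + 1e-9, crude_step),
                  np.arange(s_lo, s_hi + 1e-9, crude_step))
    best_lg, best_ls, _ = min(crude, key=lambda c: (c[2], c[0], c[1]))
    refined = sweep(
        np.arange(best_lg - crude_step, best_lg + crude_step + 1e-9, refine_step),
        np.arange(best_ls - crude_step, best_ls + crude_step + 1e-9, refine_step),
    )
    lg, ls, rmsecv = min(refined, key=lambda c: (c[2], c[0], c[1]))
    return GridSearchResult(
        crude_grid=crude, refined_grid=refined,
        best_gamma=2.0**lg, best_sigma2=2.0**ls, best_rmsecv=rmsecv,
    )
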