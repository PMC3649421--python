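"""FastICA source separation and sensitive-wavelength (SW) selection.

The noise-free ICA model treats the N preprocessed spectra as linear mixtures
x = A·s of m statistically independent wavelength-domain sources s (each a
pseudo-spectrum over the K channels). Estimation follows the fast fixed-point
algorithm: centre each spectrum, whiten via the eigen-decomposition of the N×N
sample covariance (retaining m directions), then run the symmetric fixed-point
iteration with a tanh (default) or cubic contrast until the rotation update
aligns with the previous one to within ``tol``. Components are ordered by the
variance they explain in the original data and sign-fixed so the
largest-magnitude source value is positive, making "the first m components"
well defined despite ICA's inherent permutation/sign indeterminacy.

Sensitive wavelengths are the channels where the source pseudo-spectra have
their strongest weights: local extrema of |s(λ)| are pooled across the first
``n_ics_used`` components and kept greedily by descending magnitude subject to
a minimum pairwise separation, with at least one SW per used component when
feasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .synthdata import SpectraSet

__all__ = [
    "ICAModel",
    "SensitiveWavelengths",
    "fastica_fit",
    "select_sensitive_wavelengths",
    "extract_sw_features",
]


class ICAConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ICAModel:
    n_components: int
    mixing: np.ndarray           # (N, m) columns map sources back to centred data
    sources: np.ndarray          # (m, K) wavelength-domain independent components
    unmixing: np.ndarray         # (m, m) rotation applied to the whitened data
    whitening: np.ndarray        # (m, N) maps centred data to the whitened space
    data_mean: np.ndarray        # (N,) per-spectrum means removed before whitening
    explained_variance: np.ndarray  # (m,) data variance carried by each component
    convergence_iterations: int
    converged: bool
    seed: int


@dataclass(frozen=True)
class SensitiveWavelengths:
    wavelengths_nm: np.ndarray       # sorted by descending weight magnitude
    source_component_index: np.ndarray
    weight_magnitude: np.ndarray
    complete: bool = True            # False when fewer candidates than requested


def _contrast(name: str):
    if name == "tanh":
        return lambda u: np.tanh(u), lambda u: 1.0 - np.tanh(u) ** 2
    if name == "cube":
        return lambda u: u**3, lambda u: 3.0 * u**2
    raise ValueError(f"unknown contrast {name!r}; use 'tanh' or 'cube'")


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(W @ W.T)
    vals = np.maximum(vals, 1e-300)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ W


def fastica_fit(
    X: np.ndarray | SpectraSet,
    n_components: int = 4,
    seed: int = 0,
    contrast: str = "tanh",
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ICAModel:
    """Estimate independent wavelength-domain components by symmetric FastICA.

    Non-convergence within ``max_iter`` raises an ``ICAConvergenceWarning`` and
    is recorded on the returned model rather than raised as an exception.
    """
    if isinstance(X, SpectraSet):
        X = X.reflectance
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if not 1 <= n_components <= min(n, k):
        raise ValueError(f"n_components must be in [1, {min(n, k)}]")
    if np.allclose(X, X[:, :1]):
        raise ValueError("data is constant; ICA undefined")
    g, g_prime = _contrast(contrast)

    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = Xc @ Xc.T / k
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    d = np.maximum(vals[order], 1e-30)
    E = vecs[:, order]
    whitening = (E / np.sqrt(d)).T          # (m, N)
    Z = whitening @ Xc                      # (m, K), cov(Z) = I

    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((n_components, n_components)))
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        U = W @ Z
        W_new = (g(U) @ Z.T) / k - np.diag(g_prime(U).mean(axis=1)) @ W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FastICA did not converge in {max_iter} iterations (lim={lim:.2e})",
            ICAConvergenceWarning,
        )

    S = W @ Z                               # (m, K), rows zero mean / unit variance
    # mixing back to the original (centred) space: Xc ≈ A S
    A = (E * np.sqrt(d)) @ W.T

    # order by explained data variance (rows of S have unit variance, so this
    # is the squared norm of the corresponding mixing column)
    explained = np.sum(A**2, axis=0)
    order = np.argsort(explained)[::-1]
    A, S, W = A[:, order], S[order], W[order]
    explained = explained[order]
    flip = np.sign(S[np.arange(n_components), np.argmax(np.abs(S), axis=1)])
    flip[flip == 0] = 1.0
    S = S * flip[:, None]
    A = A * flip[None, :]
    W = W * flip[:, None]

    return ICAModel(
        n_components=n_components, mixing=A, sources=S, unmixing=W,
        whitening=whitening, data_mean=mean, explained_variance=explained,
        convergence_iterations=iteration, converged=converged, seed=seed,
    )


def _local_extrema_indices(magnitude: np.ndarray) -> np.ndarray:
    """Indices of local maxima of |s(λ)|, including dominant boundary points."""
    idx = argrelextrema(magnitude, np.greater_equal, order=1)[0]
    # greater_equal admits flat runs; deduplicate plateaus to their first index
    keep = []
    for i in idx:
        if not keep or magnitude[i] != magnitude[keep[-1]] or i - keep[-1] > 1:
            keep.append(int(i))
    ends = [i for i in (0, magnitude.size - 1) if i not in keep]
    for i in ends:
        neighbour = 1 if i == 0 else magnitude.size - 2
        if magnitude[i] > magnitude[neighbour]:
            keep.append(i)
    return np.array(sorted(keep), dtype=int)


def select_sensitive_wavelengths(
    model: ICAModel,
    wavelengths_nm: np.ndarray,
    n_sws: int = 6,
    n_ics_used: int = 4,
    min_separation_nm: float = 10.0,
    smoothing_half_width: int = 3,
) -> SensitiveWavelengths:
    """Pick the ``n_sws`` strongest source weights as sensitive wavelengths.

    Candidates are the local extrema of |s(λ)| of the first ``n_ics_used``
    components; they are retained greedily by descending magnitude with a
    pairwise separation of at least ``min_separation_nm``, guaranteeing one SW
    per used component when feasible. Because the source estimates inherit
    per-channel noise, each pseudo-spectrum is lightly smoothed (quadratic
    local fit of window 2·``smoothing_half_width``+1) before extrema are
    located, which consolidates one noisy band into one candidate at its
    centre. Selection is deterministic given the fitted model.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if model.sources.shape[1] != wavelengths_nm.size:
        raise ValueError("wavelength grid does not match the fitted sources")
    if not 1 <= n_ics_used <= model.n_components:
        raise ValueError(f"n_ics_used must be in [1, {model.n_components}]")
    if n_sws < n_ics_used:
        raise ValueError("n_sws must be >= n_ics_used")

    if smoothing_half_width > 0:
        from .preprocess import sg_filter_matrix

        M = sg_filter_matrix(wavelengths_nm.size, smoothing_half_width, 2, 0)
        sources = model.sources[:n_ics_used] @ M.T
    else:
        sources = model.sources[:n_ics_used]

    candidates: list[tuple[float, float, int]] = []  # (|weight|, wavelength, component)
    for comp in range(n_ics_used):
        mag = np.abs(sources[comp])
        for i in _local_extrema_indices(mag):
            candidates.append((float(mag[i]), float(wavelengths_nm[i]), comp))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    def separated(wl: float, chosen: list[tuple[float, float, int]]) -> bool:
        return all(abs(wl - c[1]) >= min_separation_nm for c in chosen)

    chosen: list[tuple[float, float, int]] = []
    for cand in candidates:
        if len(chosen) == n_sws:
            break
        if separated(cand[1], chosen):
            chosen.append(cand)

    # at-least-one-per-used-IC guarantee: swap in the best candidate of any
    # missing component for the weakest selected SW of an over-represented one
    for comp in range(n_ics_used):
        if any(c[2] == comp for c in chosen):
            continue
        replacement = None
        for cand in candidates:
            if cand[2] != comp:
                continue
            others = [c for c in chosen if c[2] != comp]
            counts = {c[2]: sum(1 for o in others if o[2] == c[2]) for c in others}
            removable = [c for c in others if counts[c[2]] > 1]
            for victim in sorted(removable, key=lambda c: c[0]):
                trial = [c for c in chosen if c is not victim]
                if separated(cand[1], trial):
                    replacement = (victim, cand)
                    break
            if replacement:
                break
        if replacement:
            victim, cand = replacement
            chosen = [c for c in chosen if c is not victim] + [cand]

    chosen.sort(key=lambda c: (-c[0], c[1]))
    complete = len(chosen) == n_sws
    if not complete:
        warnings.warn(
            f"only {len(chosen)} sensitive wavelengths satisfy the separation "
            f"constraint (requested {n_sws})",
            UserWarning,
        )
    return SensitiveWavelengths(
        wavelengths_nm=np.array([c[1] for c in chosen]),
        source_component_index=np.array([c[2] for c in chosen], dtype=int),
        weight_magnitude=np.array([c[0] for c in chosen]),
        complete=complete,
    )


def extract_sw_features(data: SpectraSet, sws: SensitiveWavelengths) -> np.ndarray:
    """Reflectance at the selected wavelengths, columns in SW order (no interpolation)."""
    cols = []
    for wl in sws.wavelengths_nm:
        matches = np.flatnonzero(np.isclose(data.wavelengths_nm, wl, rtol=0, atol=1e-9))
        if matches.size != 1:
            raise ValueError(f"wavelength {wl} nm is not on the data grid")
        cols.append(int(matches[0]))
    return data.reflectance[:, cols]
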