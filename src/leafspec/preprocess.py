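"""Spectral pretreatment: end-trimming and Savitzky–Golay smoothing/derivatives.

Handheld spectroradiometers are noisy at the extremes of their sensitivity
range, so the first and last channels are trimmed (default 75 points each,
turning a 325–1075 nm scan into 400–1000 nm). Smoothing uses a Savitzky–Golay
filter — a sliding local least-squares polynomial fit — with a default window
of 7 points (3-1-3) and quadratic order. Edge points are handled by refitting
the polynomial on the truncated asymmetric window, which keeps the output
length equal to the input without fabricating data. Derivatives are returned
per nm (the index-domain derivative divided by the grid step raised to the
derivative order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .synthdata import SpectraSet

__all__ = ["PreprocessConfig", "trim_ends", "savitzky_golay", "to_absorbance", "sg_filter_matrix"]


@dataclass(frozen=True)
class PreprocessConfig:
    trim_head: int = 75
    trim_tail: int = 75
    sg_half_width: int = 3
    sg_polyorder: int = 2
    sg_derivative: int = 0

    def validate(self, n_points: int | None = None) -> None:
        if self.trim_head < 0 or self.trim_tail < 0:
            raise ValueError("trim counts must be non-negative")
        if self.sg_half_width < 1:
            raise ValueError("sg_half_width must be >= 1")
        window = 2 * self.sg_half_width + 1
        if self.sg_polyorder < 0 or self.sg_polyorder >= window:
            raise ValueError(f"sg_polyorder must be in [0, {window - 1})")
        # truncated edge windows have sg_half_width+1 points; the fit must stay determined
        if self.sg_polyorder > self.sg_half_width:
            raise ValueError("sg_polyorder must not exceed sg_half_width (edge refit)")
        if self.sg_derivative not in (0, 1, 2):
            raise ValueError("sg_derivative must be 0, 1 or 2")
        if self.sg_derivative > self.sg_polyorder:
            raise ValueError("sg_derivative must not exceed sg_polyorder")
        if n_points is not None and window > n_points:
            raise ValueError(f"window {window} exceeds spectrum length {n_points}")


def trim_ends(data: SpectraSet, trim_head: int, trim_tail: int) -> SpectraSet:
    """Drop the first ``trim_head`` and last ``trim_tail`` wavelength channels."""
    if trim_head < 0 or trim_tail < 0:
        raise ValueError("trim counts must be non-negative")
    k = data.n_wavelengths
    if trim_head + trim_tail >= k:
        raise ValueError(
            f"cannot trim {trim_head}+{trim_tail} points from a {k}-point spectrum"
        )
    stop = k - trim_tail
    return replace(
        data,
        wavelengths_nm=data.wavelengths_nm[trim_head:stop],
        reflectance=data.reflectance[:, trim_head:stop],
    )


def _fit_row(offsets: np.ndarray, polyorder: int, derivative: int) -> np.ndarray:
    """Weights mapping window samples to the derivative of the LS polynomial at 0."""
    V = np.vander(offsets, polyorder + 1, increasing=True)  # columns: u^0 .. u^p
    # row of the pseudoinverse picking the u^derivative coefficient
    coeff_row = np.linalg.pinv(V)[derivative]
    return math.factorial(derivative) * coeff_row


def sg_filter_matrix(
    n_points: int, half_width: int, polyorder: int, derivative: int
) -> np.ndarray:
    """Dense K×K Savitzky–Golay operator with truncated asymmetric edge windows.

    Row i holds the weights producing output point i; interior rows share the
    classical symmetric-window convolution weights, edge rows refit the
    polynomial on the window clipped to the array bounds.
    """
    h = half_width
    M = np.zeros((n_points, n_points))
    interior = _fit_row(np.arange(-h, h + 1, dtype=float), polyorder, derivative)
    for i in range(n_points):
        lo, hi = max(0, i - h), min(n_points - 1, i + h)
        if hi - lo == 2 * h:
            M[i, lo : hi + 1] = interior
        else:
            offsets = np.arange(lo - i, hi - i + 1, dtype=float)
            M[i, lo : hi + 1] = _fit_row(offsets, polyorder, derivative)
    return M


def savitzky_golay(data: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Apply the Savitzky–Golay filter of the configured window/order/derivative."""
    k = data.n_wavelengths
    config.validate(n_points=k)
    M = sg_filter_matrix(k, config.sg_half_width, config.sg_polyorder, config.sg_derivative)
    out = data.reflectance @ M.T
    if config.sg_derivative > 0:
        steps = np.diff(data.wavelengths_nm)
        step = float(steps[0])
        if not np.allclose(steps, step, rtol=1e-8, atol=1e-10):
            raise ValueError("derivative output requires a uniform wavelength grid")
        out = out / step**config.sg_derivative
    return replace(data, reflectance=out)


def to_absorbance(data: SpectraSet, floor: float = 1e-4) -> SpectraSet:
    """Pseudo-absorbance transform log10(1/R); reflectance floored at ``floor``."""
    refl = np.maximum(data.reflectance, floor)
    return replace(data, reflectance=np.log10(1.0 / refl))
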