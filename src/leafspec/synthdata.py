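"""Synthetic leaf-reflectance spectra with known concentration→spectrum structure.

Real Vis/NIR leaf spectra share a characteristic morphology: a low visible
plateau around 10% reflectance with a small green peak near 560–580 nm, a
steep "red edge" between ~690 and 740 nm rising to a near-infrared plateau of
30–70% reflectance, and a water-related absorption dip near 960 nm. The
generator here reproduces that morphology on a 1-nm grid (default 325–1075 nm)
and injects a trace-element signal as concentration-dependent Gaussian
absorption bands, optionally passed through a saturating link so that the
concentration→spectrum relationship is mildly nonlinear. Every draw is a pure
function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SpectraSet",
    "ELEMENT_CONC_RANGES_PPM",
    "generate_dataset",
    "split_calibration_validation",
    "write_spectra_csv",
    "write_targets_csv",
]

#: Printed concentration ranges (ppm) for the two supported trace elements.
ELEMENT_CONC_RANGES_PPM: dict[str, tuple[float, float]] = {
    "Fe": (39.951, 134.254),
    "Zn": (9.085, 49.927),
}

_DEFAULT_BAND_CENTERS_NM = (560.0, 680.0, 960.0)
_DEFAULT_BAND_WIDTHS_NM = (18.0, 14.0, 28.0)
# one physiological driver: all bands respond with the same sensitivity, so the
# concentration signal is a rank-one spectral pattern through the saturating link
_DEFAULT_BAND_GAIN = (2e-3, 2e-3, 2e-3)


@dataclass(frozen=True)
class SpectraSet:
    """A wavelength grid plus an N×K reflectance matrix and sample metadata.

    Attributes
    ----------
    wavelengths_nm : ndarray, shape (K,)
        Strictly increasing wavelength grid in nanometres.
    reflectance : ndarray, shape (N, K)
        Unitless reflectance relative to a white reference; finite, in [0, 2).
    sample_ids : list of str, length N
    targets_ppm : ndarray of shape (N,), optional
        Element concentration per sample, strictly positive.
    element_label : str, optional
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]
    targets_ppm: Optional[np.ndarray] = None
    element_label: Optional[str] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1:
            raise ValueError("wavelengths_nm must be a 1-D vector")
        if refl.ndim != 2:
            raise ValueError("reflectance must be an N×K matrix")
        if refl.shape[1] != wl.size:
            raise ValueError(
                f"reflectance has {refl.shape[1]} columns but grid has {wl.size} points"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance contains non-finite values")
        if len(self.sample_ids) != refl.shape[0]:
            raise ValueError("sample_ids length must match number of spectra")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.targets_ppm is not None:
            t = np.asarray(self.targets_ppm, dtype=float)
            object.__setattr__(self, "targets_ppm", t)
            if t.shape != (refl.shape[0],):
                raise ValueError("targets_ppm must have one value per sample")
            if not np.all(t > 0):
                raise ValueError("targets_ppm must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def with_targets(self, targets_ppm: np.ndarray, element_label: str | None = None) -> "SpectraSet":
        return replace(self, targets_ppm=np.asarray(targets_ppm, dtype=float),
                       element_label=element_label or self.element_label)

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset in the given order; targets follow when present."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm,
            reflectance=self.reflectance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            targets_ppm=None if self.targets_ppm is None else self.targets_ppm[idx],
            element_label=self.element_label,
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic spectra generator.

    ``band_gain`` is the reflectance depth per ppm of each concentration band;
    ``nonlinearity`` controls a saturating link applied to the raw band depth
    (0 means exactly affine in concentration); ``plateau_spread`` is the
    half-range of the per-sample near-infrared plateau around 0.50, so the
    default 0.20 yields plateaus uniform in [0.30, 0.70].
    """

    n_samples: int = 90
    wavelength_start_nm: float = 325.0
    wavelength_end_nm: float = 1075.0
    wavelength_step_nm: float = 1.0
    element: str = "Fe"
    conc_range_ppm: Optional[tuple[float, float]] = None
    band_centers_nm: tuple[float, ...] = _DEFAULT_BAND_CENTERS_NM
    band_widths_nm: tuple[float, ...] = _DEFAULT_BAND_WIDTHS_NM
    band_gain: tuple[float, ...] = _DEFAULT_BAND_GAIN
    nonlinearity: float = 10.0
    noise_sd: float = 0.002
    plateau_spread: float = 0.20
    seed: int = 0

    def resolved_conc_range(self) -> tuple[float, float]:
        if self.conc_range_ppm is not None:
            return self.conc_range_ppm
        try:
            return ELEMENT_CONC_RANGES_PPM[self.element]
        except KeyError:
            raise ValueError(f"unknown element {self.element!r}; provide conc_range_ppm") from None

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.wavelength_step_nm <= 0 or self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength grid must be increasing with positive step")
        low, high = self.resolved_conc_range()
        if not low < high:
            raise ValueError("conc_range_ppm must satisfy low < high")
        if low <= 0:
            raise ValueError("concentrations must be positive")
        n_bands = len(self.band_centers_nm)
        if n_bands == 0:
            raise ValueError("at least one concentration band is required")
        if len(self.band_widths_nm) != n_bands or len(self.band_gain) != n_bands:
            raise ValueError("band_centers_nm, band_widths_nm and band_gain must have equal length")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValueError("band widths must be positive")
        if self.nonlinearity < 0:
            raise ValueError("nonlinearity must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plateau_spread < 0:
            raise ValueError("plateau_spread must be >= 0")

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm) / self.wavelength_step_nm)) + 1
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(n)


def _baseline_spectrum(wl: np.ndarray, plateau: float) -> np.ndarray:
    """Leaf-like baseline: visible plateau + green peak + red edge + 960 nm dip."""
    base = np.full_like(wl, 0.10)
    green = 0.05 * np.exp(-0.5 * ((wl - 570.0) / 10.0) ** 2)
    # logistic red edge centred at 715 nm spanning ~690–740 nm
    edge = (plateau - 0.10) / (1.0 + np.exp(-(wl - 715.0) / 8.0))
    water_dip = 0.06 * plateau * np.exp(-0.5 * ((wl - 960.0) / 22.0) ** 2)
    return base + green + edge - water_dip


def _saturating_link(raw_depth: np.ndarray, nonlinearity: float) -> np.ndarray:
    """Exponential-saturation link; identity in the limit nonlinearity → 0."""
    if nonlinearity == 0:
        return raw_depth
    return (1.0 - np.exp(-nonlinearity * raw_depth)) / nonlinearity


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Draw a seeded synthetic dataset of leaf reflectance spectra.

    Each spectrum is a sample-specific baseline (near-infrared plateau drawn
    uniformly from 0.50 ± plateau_spread) minus concentration-dependent
    Gaussian absorption bands of raw depth ``band_gain · c`` passed through the
    saturating link, plus i.i.d. Gaussian noise. Targets are uniform over the
    element's concentration range. Identical configs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    n = config.n_samples
    low, high = config.resolved_conc_range()

    conc = rng.uniform(low, high, size=n)
    plateaus = 0.50 + config.plateau_spread * rng.uniform(-1.0, 1.0, size=n)

    spectra = np.empty((n, wl.size))
    centers = np.asarray(config.band_centers_nm)
    widths = np.asarray(config.band_widths_nm)
    gains = np.asarray(config.band_gain)
    # unit-height band shapes, one row per band
    shapes = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    for i in range(n):
        raw_depths = gains * conc[i]
        depths = _saturating_link(raw_depths, config.nonlinearity)
        spectra[i] = _baseline_spectrum(wl, plateaus[i]) - depths @ shapes
    if config.noise_sd > 0:
        spectra += rng.normal(0.0, config.noise_sd, size=spectra.shape)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    return SpectraSet(wl, spectra, ids, targets_ppm=conc, element_label=config.element)


def split_calibration_validation(
    data: SpectraSet, n_calibration: int, seed: int
) -> tuple[SpectraSet, SpectraSet]:
    """Seeded disjoint split; each split keeps ascending original sample order."""
    n = data.n_samples
    if not 0 < n_calibration < n:
        raise ValueError(
            f"n_calibration must be in (0, {n}); got {n_calibration} "
            "(both splits must be non-empty)"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_calibration])
    val_idx = np.sort(perm[n_calibration:])
    return data.subset(cal_idx), data.subset(val_idx)


def write_spectra_csv(data: SpectraSet, path: str | Path) -> None:
    """Write the wide-format spectra CSV: `wavelength_nm`, one column per sample."""
    df = pd.DataFrame(
        data.reflectance.T, index=data.wavelengths_nm, columns=data.sample_ids
    )
    df.index.name = "wavelength_nm"
    df.to_csv(path, float_format="%.12g", lineterminator="\n")


def write_targets_csv(data: SpectraSet, path: str | Path) -> None:
    """Write the targets CSV: columns `sample_id,<element>_ppm`."""
    if data.targets_ppm is None:
        raise ValueError("SpectraSet has no targets to write")
    element = data.element_label or "element"
    df = pd.DataFrame(
        {"sample_id": data.sample_ids, f"{element}_ppm": data.targets_ppm}
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
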