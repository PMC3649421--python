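"""Reading, writing and validating the CSV spectra/target formats.

The on-disk convention is plain CSV: a wide spectra file whose first column is
``wavelength_nm`` with one column per sample (reflectance as decimal
fractions), and a targets file with ``sample_id`` and ``<element>_ppm``
columns. Internally spectra are oriented samples × wavelengths.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import SpectraSet, write_spectra_csv, write_targets_csv

__all__ = [
    "DatasetBundle",
    "read_spectra",
    "read_targets",
    "attach_targets",
    "load_dataset",
    "write_spectra_csv",
    "write_targets_csv",
]


class SpectraFormatError(ValueError):
    """Raised when an input file violates the spectra/targets CSV contract."""


@dataclass(frozen=True)
class DatasetBundle:
    spectra: SpectraSet
    source_paths: tuple[str, ...]
    checksums: tuple[str, ...]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide-format spectra CSV into a SpectraSet.

    Validates the header (first column ``wavelength_nm``, unique sample ids),
    numeric cells (errors carry row/column coordinates) and a strictly
    increasing wavelength grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    columns = header.split(",")
    if not columns or columns[0] != "wavelength_nm":
        raise SpectraFormatError(
            f"{path}: first header column must be 'wavelength_nm', got {columns[:1]!r}"
        )
    sample_ids = columns[1:]
    if len(sample_ids) == 0:
        raise SpectraFormatError(f"{path}: no sample columns found")
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise SpectraFormatError(f"{path}: duplicated sample id column {sid!r}")
        seen.add(sid)

    df = pd.read_csv(path, header=0, names=["wavelength_nm", *sample_ids], dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraFormatError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at data row {i + 1}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy()

    wavelengths = values[:, 0]
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(f"{path}: wavelengths are not strictly increasing")
    return SpectraSet(
        wavelengths_nm=wavelengths,
        reflectance=values[:, 1:].T,
        sample_ids=sample_ids,
    )


def read_targets(path: str | Path, element: str) -> pd.Series:
    """Read a targets CSV and return a Series of concentrations indexed by id."""
    path = Path(path)
    df = pd.read_csv(path)
    col = f"{element}_ppm"
    if "sample_id" not in df.columns:
        raise SpectraFormatError(f"{path}: missing 'sample_id' column")
    if col not in df.columns:
        raise SpectraFormatError(
            f"{path}: missing '{col}' column (columns: {list(df.columns)})"
        )
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise SpectraFormatError(f"{path}: duplicated sample ids in targets: {dupes}")
    series = pd.Series(df[col].to_numpy(dtype=float), index=ids)
    if not np.all(np.isfinite(series.to_numpy())):
        raise SpectraFormatError(f"{path}: non-finite concentration values")
    if (series <= 0).any():
        bad = sorted(series.index[series <= 0])
        raise SpectraFormatError(f"{path}: non-positive concentrations for ids {bad}")
    return series


def attach_targets(data: SpectraSet, path: str | Path, element: str) -> SpectraSet:
    """Join concentrations to spectra by sample id; any unmatched id is an error."""
    targets = read_targets(path, element)
    missing = [sid for sid in data.sample_ids if sid not in targets.index]
    if missing:
        raise SpectraFormatError(
            f"{path}: no target row for sample ids {missing}"
        )
    vec = targets.loc[data.sample_ids].to_numpy()
    return data.with_targets(vec, element_label=element)


def load_dataset(spectra_path: str | Path, targets_path: str | Path, element: str) -> DatasetBundle:
    """Read spectra + targets and record provenance (paths and SHA-256 sums)."""
    spectra_path, targets_path = Path(spectra_path), Path(targets_path)
    data = attach_targets(read_spectra(spectra_path), targets_path, element)
    return DatasetBundle(
        spectra=data,
        source_paths=(str(spectra_path), str(targets_path)),
        checksums=(_sha256(spectra_path), _sha256(targets_path)),
    )
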