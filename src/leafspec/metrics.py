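"""Calibration/prediction error metrics and the cross-model comparison table.

RMSEC/RMSEP is the root-mean-square error √(Σ(ŷᵢ−yᵢ)²/Iₚ) over the
calibration or prediction set, bias the mean signed error Σ(ŷᵢ−yᵢ)/Iₚ, both
in concentration units (ppm). R² defaults to the squared Pearson correlation
between predicted and measured values (the usual predicted-vs-reference
scatter convention in chemometrics); the 1 − SSE/SST variant is available via
``kind="explained"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "rmse", "bias", "r_squared", "compare_models"]


@dataclass(frozen=True)
class EvaluationReport:
    model_label: str
    element: str
    split: str              # "calibration" | "validation"
    n: int
    n_variables: int        # input variables of the regressor (PCs/LVs/SWs or K)
    r_squared: float
    rmse_ppm: float
    bias_ppm: float


def _check_pair(predicted: np.ndarray, measured: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    m = np.asarray(measured, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != m.size:
        raise ValueError(f"length mismatch: {p.size} vs {m.size}")
    return p, m


def rmse(predicted: np.ndarray, measured: np.ndarray) -> float:
    p, m = _check_pair(predicted, measured)
    return float(np.sqrt(np.mean((p - m) ** 2)))


def bias(predicted: np.ndarray, measured: np.ndarray) -> float:
    p, m = _check_pair(predicted, measured)
    return float(np.mean(p - m))


def r_squared(predicted: np.ndarray, measured: np.ndarray, kind: str = "pearson") -> float:
    """Coefficient of determination between predicted and measured values."""
    p, m = _check_pair(predicted, measured)
    if p.size < 2:
        raise ValueError("r_squared requires at least 2 samples")
    if np.std(m) == 0:
        raise ValueError("measured values have zero variance")
    if kind == "pearson":
        if np.std(p) == 0:
            raise ValueError("predicted values have zero variance")
        c = np.corrcoef(p, m)[0, 1]
        return float(c * c)
    if kind == "explained":
        sse = float(np.sum((p - m) ** 2))
        sst = float(np.sum((m - m.mean()) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown kind {kind!r}; use 'pearson' or 'explained'")


def evaluate(
    model_label: str, element: str, split: str, n_variables: int,
    predicted: np.ndarray, measured: np.ndarray,
) -> EvaluationReport:
    p, m = _check_pair(predicted, measured)
    return EvaluationReport(
        model_label=model_label, element=element, split=split,
        n=p.size, n_variables=n_variables,
        r_squared=r_squared(p, m), rmse_ppm=rmse(p, m), bias_ppm=bias(p, m),
    )


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Rank models by ascending RMSE; ties broken by model label.

    All reports must describe the same element and split (comparisons across
    elements are meaningless in ppm).
    """
    if not reports:
        raise ValueError("no reports to compare")
    elements = {r.element for r in reports}
    if len(elements) > 1:
        raise ValueError(f"reports mix elements {sorted(elements)}")
    splits = {r.split for r in reports}
    if len(splits) > 1:
        raise ValueError(f"reports mix splits {sorted(splits)}")
    rows = sorted(reports, key=lambda r: (r.rmse_ppm, r.model_label))
    return pd.DataFrame(
        {
            "model": [r.model_label for r in rows],
            "element": [r.element for r in rows],
            "split": [r.split for r in rows],
            "n": [r.n for r in rows],
            "variables": [r.n_variables for r in rows],
            "r2": [r.r_squared for r in rows],
            "rmse_ppm": [r.rmse_ppm for r in rows],
            "bias_ppm": [r.bias_ppm for r in rows],
        }
    )
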