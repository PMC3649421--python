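"""End-to-end calibration workflows: PLS, PCA-LS-SVM, LV-LS-SVM, ICA-LS-SVM.

Each workflow shares the same front end — read CSVs, trim the noisy channel
ends, Savitzky–Golay smooth, split into calibration/validation sets — and
differs only in the regressor inputs:

* ``pls``        — full-spectrum PLS, LV count selected by leave-one-out PRESS;
* ``pca_lssvm``  — principal-component scores feeding a grid-searched LS-SVM;
* ``lv_lssvm``   — PLS latent-variable scores feeding an LS-SVM;
* ``ica_lssvm``  — reflectance at FastICA-selected sensitive wavelengths
                   feeding an LS-SVM.

All feature extractors and scalers are fitted on the calibration split only
(``fit_on="all"`` mimics fitting on the pooled data). Runs are reproducible
from the config alone, and a run log records intermediate shapes and chosen
hyperparameters. Fitted models serialize to a versioned JSON container.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as spectra_io
from . import metrics
from .ica import fastica_fit, select_sensitive_wavelengths, extract_sw_features, SensitiveWavelengths
from .latent import (
    pca_fit, pca_transform, pls_fit, pls_predict, pls_scores, select_lvs_by_press,
)
from .lssvm import (
    DEFAULT_GAMMA_LOG2_RANGE, DEFAULT_SIGMA2_LOG2_RANGE,
    grid_search, lssvm_fit, lssvm_predict,
)
from .preprocess import PreprocessConfig, savitzky_golay, to_absorbance, trim_ends
from .synthdata import SpectraSet, split_calibration_validation

__all__ = [
    "PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_on_data",
    "save_model_json", "load_model_json", "predict_from_artifact",
]

logger = logging.getLogger("leafspec.pipeline")

MODEL_KINDS = ("pls", "pca_lssvm", "lv_lssvm", "ica_lssvm")
FORMAT_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    model_kind: str = "ica_lssvm"
    element: str = "Fe"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    absorbance: bool = False
    n_features: Optional[int] = None    # PCs/SWs (default 6); LVs default to PRESS choice
    max_lvs: int = 15
    n_ics: int = 4
    min_separation_nm: float = 10.0
    ica_contrast: str = "tanh"
    gamma_log2_range: tuple[float, float] = DEFAULT_GAMMA_LOG2_RANGE
    sigma2_log2_range: tuple[float, float] = DEFAULT_SIGMA2_LOG2_RANGE
    folds: int = 10
    n_calibration: int = 70
    fit_on: str = "calibration"         # "calibration" | "all"
    seed: int = 0

    def validate(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.fit_on not in ("calibration", "all"):
            raise ValueError("fit_on must be 'calibration' or 'all'")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class PipelineResult:
    config: PipelineConfig
    artifact: dict
    calibration_report: metrics.EvaluationReport
    validation_report: metrics.EvaluationReport
    calibration_ids: list[str]
    validation_ids: list[str]
    sensitive_wavelengths: Optional[SensitiveWavelengths] = None


def _preprocess(data: SpectraSet, config: PipelineConfig) -> SpectraSet:
    pp = config.preprocess
    out = trim_ends(data, pp.trim_head, pp.trim_tail)
    out = savitzky_golay(out, pp)
    if config.absorbance:
        out = to_absorbance(out)
    return out


def _fit_features(cal: SpectraSet, fit_set: SpectraSet, config: PipelineConfig):
    """Fit the feature extractor on ``fit_set``; return (extractor dict, fn)."""
    kind = config.model_kind
    if kind == "pca_lssvm":
        n_pcs = config.n_features or 6
        model = pca_fit(fit_set.reflectance, n_pcs)
        logger.info(
            "PCA: %d components, cumulative variance %.1f%%",
            n_pcs, 100 * float(model.explained_variance_fraction.sum()),
        )
        extractor = {
            "type": "pca",
            "mean": model.mean_spectrum.tolist(),
            "loadings": model.loadings.tolist(),
            "cumulative_variance_fraction": float(model.explained_variance_fraction.sum()),
        }
        return extractor, lambda d: pca_transform(model, d.reflectance)
    if kind == "lv_lssvm":
        n_lvs, press = select_lvs_by_press(
            fit_set.reflectance, fit_set.targets_ppm, config.max_lvs
        )
        if config.n_features is not None:
            n_lvs = config.n_features
        model = pls_fit(fit_set.reflectance, fit_set.targets_ppm, n_lvs)
        logger.info("PLS scores: %d LVs (PRESS minimum)", model.n_lvs)
        extractor = {
            "type": "pls_scores",
            "x_mean": model.x_mean.tolist(),
            "weights": model.weights.tolist(),
            "x_loadings": model.x_loadings.tolist(),
            "n_lvs": model.n_lvs,
            "press_curve": press.tolist(),
        }
        return extractor, lambda d: pls_scores(model, d.reflectance)
    if kind == "ica_lssvm":
        n_sws = config.n_features or 6
        ica_model = fastica_fit(
            fit_set.reflectance, n_components=config.n_ics,
            seed=config.seed, contrast=config.ica_contrast,
        )
        sws = select_sensitive_wavelengths(
            ica_model, fit_set.wavelengths_nm, n_sws=n_sws,
            n_ics_used=config.n_ics, min_separation_nm=config.min_separation_nm,
        )
        logger.info(
            "ICA: %d ICs → %d SWs at %s nm",
            config.n_ics, sws.wavelengths_nm.size, np.round(sws.wavelengths_nm, 1),
        )
        extractor = {
            "type": "sensitive_wavelengths",
            "wavelengths_nm": sws.wavelengths_nm.tolist(),
            "source_component_index": sws.source_component_index.tolist(),
            "weight_magnitude": sws.weight_magnitude.tolist(),
            "converged": ica_model.converged,
        }
        return extractor, lambda d: extract_sw_features(d, sws), sws
    raise AssertionError(kind)


def run_pipeline_on_data(config: PipelineConfig, data: SpectraSet) -> PipelineResult:
    """Run one workflow on an in-memory SpectraSet with attached targets."""
    config.validate()
    if data.targets_ppm is None:
        raise ValueError("pipeline requires targets attached to the spectra")
    logger.info(
        "pipeline %s/%s: %d samples × %d wavelengths",
        config.model_kind, config.element, data.n_samples, data.n_wavelengths,
    )
    pre = _preprocess(data, config)
    logger.info("preprocessed: %d wavelengths (%.0f–%.0f nm)",
                pre.n_wavelengths, pre.wavelengths_nm[0], pre.wavelengths_nm[-1])
    cal, val = split_calibration_validation(pre, config.n_calibration, config.seed)
    fit_set = pre if config.fit_on == "all" else cal
    y_cal, y_val = cal.targets_ppm, val.targets_ppm

    artifact: dict = {
        "format_version": FORMAT_VERSION,
        "model_kind": config.model_kind,
        "element": config.element,
        "preprocess": asdict(config.preprocess),
        "absorbance": config.absorbance,
        "wavelengths_nm": pre.wavelengths_nm.tolist(),
        "calibration_ids": cal.sample_ids,
        "validation_ids": val.sample_ids,
        "seed": config.seed,
    }
    sws = None

    if config.model_kind == "pls":
        n_lvs, press = select_lvs_by_press(cal.reflectance, y_cal, config.max_lvs)
        if config.n_features is not None:
            n_lvs = config.n_features
        model = pls_fit(cal.reflectance, y_cal, n_lvs, press_curve=press)
        logger.info("PLS: %d LVs selected by LOO PRESS", model.n_lvs)
        pred_cal = pls_predict(model, cal.reflectance)
        pred_val = pls_predict(model, val.reflectance)
        n_vars = model.n_lvs
        artifact["regressor"] = {
            "type": "pls",
            "n_lvs": model.n_lvs,
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean,
            "regression_vector": model.regression_vector.tolist(),
            "press_curve": press.tolist(),
        }
    else:
        fitted = _fit_features(cal, fit_set, config)
        if len(fitted) == 3:
            extractor, feature_fn, sws = fitted
        else:
            extractor, feature_fn = fitted
        F_cal = feature_fn(cal)
        F_val = feature_fn(val)
        logger.info("features: calibration %s, validation %s", F_cal.shape, F_val.shape)
        gs = grid_search(
            F_cal, y_cal,
            gamma_log2_range=config.gamma_log2_range,
            sigma2_log2_range=config.sigma2_log2_range,
            folds=config.folds, seed=config.seed,
        )
        logger.info(
            "grid search: γ=%.4g σ²=%.4g RMSECV=%.3f ppm",
            gs.best_gamma, gs.best_sigma2, gs.best_rmsecv,
        )
        model = lssvm_fit(F_cal, y_cal, gamma=gs.best_gamma, sigma2=gs.best_sigma2)
        pred_cal = lssvm_predict(model, F_cal)
        pred_val = lssvm_predict(model, F_val)
        n_vars = F_cal.shape[1]
        artifact["feature_extractor"] = extractor
        artifact["regressor"] = {
            "type": "lssvm",
            "kernel": model.kernel,
            "gamma": model.gamma,
            "sigma2": model.sigma2,
            "support_values": model.support_values.tolist(),
            "bias": model.bias,
            "feature_center": model.feature_center.tolist(),
            "feature_scale": model.feature_scale.tolist(),
            "training_inputs": model.training_inputs.tolist(),
            "best_rmsecv_ppm": gs.best_rmsecv,
        }

    artifact["n_variables"] = int(n_vars)
    label = config.model_kind.replace("_", "-").upper().replace("LSSVM", "LS-SVM")
    cal_report = metrics.evaluate(label, config.element, "calibration", n_vars, pred_cal, y_cal)
    val_report = metrics.evaluate(label, config.element, "validation", n_vars, pred_val, y_val)
    logger.info(
        "validation: R²=%.4f RMSEP=%.4f ppm bias=%.4f ppm",
        val_report.r_squared, val_report.rmse_ppm, val_report.bias_ppm,
    )
    return PipelineResult(
        config=config, artifact=artifact,
        calibration_report=cal_report, validation_report=val_report,
        calibration_ids=cal.sample_ids, validation_ids=val.sample_ids,
        sensitive_wavelengths=sws,
    )


def run_pipeline(
    config: PipelineConfig, spectra_path: str | Path, targets_path: str | Path
) -> PipelineResult:
    """Run one workflow from the CSV pair on disk."""
    bundle = spectra_io.load_dataset(spectra_path, targets_path, config.element)
    logger.info("loaded %s (sha256 %s…)", bundle.source_paths[0], bundle.checksums[0][:12])
    return run_pipeline_on_data(config, bundle.spectra)


def save_model_json(result: PipelineResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.artifact, indent=1), encoding="utf-8")


def load_model_json(path: str | Path) -> dict:
    artifact = json.loads(Path(path).read_text(encoding="utf-8"))
    if artifact.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {artifact.get('format_version')}")
    return artifact


def predict_from_artifact(artifact: dict, data: SpectraSet) -> np.ndarray:
    """Apply a serialized model to raw spectra on the original wavelength grid."""
    pp = PreprocessConfig(**artifact["preprocess"])
    pre = savitzky_golay(trim_ends(data, pp.trim_head, pp.trim_tail), pp)
    if artifact.get("absorbance"):
        pre = to_absorbance(pre)
    if not np.allclose(pre.wavelengths_nm, np.asarray(artifact["wavelengths_nm"])):
        raise ValueError("wavelength grid does not match the fitted model")
    reg = artifact["regressor"]
    if reg["type"] == "pls":
        b = np.asarray(reg["regression_vector"])
        return reg["y_mean"] + (pre.reflectance - np.asarray(reg["x_mean"])) @ b
    fx = artifact["feature_extractor"]
    if fx["type"] == "pca":
        F = (pre.reflectance - np.asarray(fx["mean"])) @ np.asarray(fx["loadings"])
    elif fx["type"] == "pls_scores":
        Xc = pre.reflectance - np.asarray(fx["x_mean"])
        W, P = np.asarray(fx["weights"]), np.asarray(fx["x_loadings"])
        F = np.zeros((Xc.shape[0], fx["n_lvs"]))
        for a in range(fx["n_lvs"]):
            t = Xc @ W[:, a]
            Xc = Xc - np.outer(t, P[:, a])
            F[:, a] = t
    elif fx["type"] == "sensitive_wavelengths":
        cols = [int(np.argmin(np.abs(pre.wavelengths_nm - wl))) for wl in fx["wavelengths_nm"]]
        if any(abs(pre.wavelengths_nm[c] - wl) > 1e-9
               for c, wl in zip(cols, fx["wavelengths_nm"])):
            raise ValueError("sensitive wavelength off the data grid")
        F = pre.reflectance[:, cols]
    else:
        raise ValueError(f"unknown feature extractor {fx['type']!r}")
    Z = (F - np.asarray(reg["feature_center"])) / np.asarray(reg["feature_scale"])
    from .lssvm import _KERNELS  # local import avoids exposing the registry
    K = _KERNELS[reg["kernel"]](Z, np.asarray(reg["training_inputs"]), reg["sigma2"])
    return K @ np.asarray(reg["support_values"]) + reg["bias"]
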