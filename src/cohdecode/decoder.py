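"""The spectro-spatial decoding model.

Fitting has two stages, both on the training trials of a single condition:

1. a per-feature Wiener filter ``H_j(f) = Pxy/Pxx`` from the cross-trial
   spectra (see :mod:`cohdecode.spectral`), giving each electrode's best
   linear estimate of the target;
2. spatial combination: the filtered outputs of all features, concatenated
   across trials in time, form a design matrix and ordinary least squares
   yields one weight ``b_j`` per feature (plus an intercept), so the final
   prediction is ``y(t) = sum_j b_j (x_j * h_j)(t) + b_0``.

The magnitudes |b_j| index how much each electrode/band contributes and,
min-max normalized, are the spatial importance maps used for anatomical
interpretation.
"""

from __future__ import annotations

import base64
import gzip
import json
import logging
from dataclasses import dataclass

import numpy as np

from .dataio import TargetSet, ValidationError
from .preprocess import FeatureTensor
from .spectral import FilterBank, apply_filterbank, cross_spectra, wiener_filter

__all__ = [
    "SpatialWeights",
    "DecodingModel",
    "fit",
    "predict",
    "fit_per_condition",
    "normalized_weights",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    b: np.ndarray          # (n_features,)
    intercept: float
    residual_var: float

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64)
        if not np.all(np.isfinite(self.b)) or not np.isfinite(self.intercept):
            raise ValidationError("spatial weights must be finite")
        if self.residual_var < 0:
            raise ValidationError("residual variance must be non-negative")


@dataclass
class DecodingModel:
    condition: str
    filterbank: FilterBank
    weights: SpatialWeights
    fs: float
    feature_ids: list
    preprocess_config: dict | None = None

    def __post_init__(self) -> None:
        if self.filterbank.n_features != self.weights.b.shape[0]:
            raise ValidationError("filterbank and weights disagree on n_features")


def fit(x: FeatureTensor, y: TargetSet, eps_rel: float = 1e-8,
        condition: str = "all", window: str = "hamming",
        intercept: bool = True, preprocess_config: dict | None = None) -> DecodingModel:
    """Fit filters and spatial weights on the trials of one condition.

    The same training trials feed both stages: the Wiener filter bank is
    estimated from their cross-trial spectra, their filtered outputs are
    concatenated in time, and the spatial weights are the least-squares
    regression of the concatenated target on them.  A rank-deficient design
    falls back to the minimum-norm solution with a logged warning.
    """
    S = cross_spectra(x, y, window=window)
    fb = wiener_filter(S, eps_rel=eps_rel)
    filtered = apply_filterbank(x, fb)            # (K, J, T)
    K, J, T = filtered.shape
    design = filtered.transpose(0, 2, 1).reshape(K * T, J)
    target = y.data.reshape(K * T)
    if intercept:
        design = np.column_stack([design, np.ones(K * T)])
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d): using minimum-norm solution",
            rank, design.shape[1])
    b = coef[:J]
    b0 = float(coef[J]) if intercept else 0.0
    resid = target - design @ coef
    weights = SpatialWeights(b=b, intercept=b0, residual_var=float(np.var(resid)))
    return DecodingModel(condition=condition, filterbank=fb, weights=weights,
                         fs=x.fs, feature_ids=list(x.feature_ids),
                         preprocess_config=preprocess_config)


def predict(model: DecodingModel, x: FeatureTensor) -> TargetSet:
    """Apply the model: per trial, sum of filtered features plus intercept."""
    if list(x.feature_ids) != list(model.feature_ids):
        raise ValidationError("feature ids do not match the fitted model")
    filtered = apply_filterbank(x, model.filterbank)
    pred = np.einsum("kjt,j->kt", filtered, model.weights.b) + model.weights.intercept
    return TargetSet(data=pred, fs=model.fs, modality="synthetic")


def fit_per_condition(x: FeatureTensor, y: TargetSet, labels,
                      eps_rel: float = 1e-8, window: str = "hamming",
                      intercept: bool = True) -> dict:
    """Fit one independent model per condition on that condition's trials."""
    labels = np.asarray(labels)
    if len(labels) != x.n_trials:
        raise ValidationError("labels/trial count mismatch")
    models = {}
    for cond in dict.fromkeys(labels.tolist()):   # preserve first-seen order
        idx = np.flatnonzero(labels == cond)
        if len(idx) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 trials")
        models[cond] = fit(x.select_trials(idx), y.select_trials(idx),
                           eps_rel=eps_rel, condition=str(cond), window=window,
                           intercept=intercept)
    return models


def effective_contributions(model: DecodingModel, x: FeatureTensor) -> np.ndarray:
    """RMS of each feature's weighted filtered output b_j * (x_j * h_j).

    A scale-invariant importance measure: rescaling a feature rescales its
    Wiener filter inversely, leaving the contribution unchanged.
    """
    filtered = apply_filterbank(x, model.filterbank)
    terms = filtered * model.weights.b[np.newaxis, :, np.newaxis]
    return np.sqrt(np.mean(terms ** 2, axis=(0, 2)))


def normalized_weights(model: DecodingModel) -> np.ndarray:
    """Min-max normalize |b| to [0, 1] for spatial importance maps.

    If all |b_j| are equal (no contrast) every feature maps to 0.5 by
    convention.
    """
    mag = np.abs(model.weights.b)
    if mag.shape[0] < 2:
        raise ValidationError("need at least 2 features to normalize")
    lo, hi = mag.min(), mag.max()
    if hi - lo <= 0:
        return np.full_like(mag, 0.5)
    return (mag - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Serialization: gzipped JSON with base64 float64 arrays
# ---------------------------------------------------------------------------

def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a)
    return {"shape": list(a.shape), "dtype": str(a.dtype),
            "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype=d["dtype"]).reshape(d["shape"])


def save_model(model: DecodingModel, path) -> None:
    fb = model.filterbank
    doc = {
        "format_version": 1,
        "condition": model.condition,
        "fs": model.fs,
        "n_samples": fb.n_samples,
        "feature_ids": [list(t) for t in model.feature_ids],
        "freqs": _enc(fb.freqs),
        "H_real": _enc(fb.H.real),
        "H_imag": _enc(fb.H.imag),
        "b": _enc(model.weights.b),
        "intercept": model.weights.intercept,
        "residual_var": model.weights.residual_var,
        "preprocess_config": model.preprocess_config,
    }
    with gzip.open(path, "wt") as f:
        json.dump(doc, f)


def load_model(path) -> DecodingModel:
    with gzip.open(path, "rt") as f:
        doc = json.load(f)
    if doc.get("format_version") != 1:
        raise ValidationError("unsupported model format version")
    H = _dec(doc["H_real"]) + 1j * _dec(doc["H_imag"])
    h = np.fft.irfft(H, n=doc["n_samples"], axis=-1)
    fb = FilterBank(freqs=_dec(doc["freqs"]), H=H, h=h, fs=doc["fs"],
                    n_samples=doc["n_samples"])
    weights = SpatialWeights(b=_dec(doc["b"]), intercept=doc["intercept"],
                             residual_var=doc["residual_var"])
    return DecodingModel(condition=doc["condition"], filterbank=fb, weights=weights,
                         fs=doc["fs"], feature_ids=[tuple(t) for t in doc["feature_ids"]],
                         preprocess_config=doc.get("preprocess_config"))
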