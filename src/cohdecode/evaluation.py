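"""Evaluation protocol: blocked cross-validation, agreement metrics, and the
spatial-weight discriminability analysis.

Decoding quality is scored by blocked 5-fold cross-validation: the trials of
each condition are split into contiguous blocks, four blocks train the model
(filters *and* spatial weights) and the held-out block is scored per trial
with Pearson's r and Lin's concordance correlation coefficient (CCC), which
additionally penalizes scale and location shifts.

Whether the per-condition spatial weights b_j carry condition information is
quantified by (a) ranking electrodes by how well their per-condition/per-fold
coefficients separate into condition clusters (K-means, between/total sum of
squares), and (b) classifying weight vectors by condition with an LDA on the
top-ranked electrodes only (selected on training folds), reporting held-out
accuracy and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import TargetSet, ValidationError
from .preprocess import FeatureTensor

__all__ = [
    "CvResult",
    "DiscriminabilityResult",
    "blocked_kfold",
    "pearson_r",
    "ccc",
    "cohen_kappa",
    "cross_validate",
    "rank_electrodes",
    "lda_discriminability",
]


@dataclass
class CvResult:
    """Per-trial cross-validation scores with the fold geometry used."""

    scores: pd.DataFrame            # columns: condition, fold, trial, r, ccc
    folds: dict                     # condition -> fold index per trial
    k: int

    def mean_r(self) -> float:
        return float(self.scores["r"].mean())

    def mean_ccc(self) -> float:
        return float(self.scores["ccc"].mean())

    def by_condition(self) -> pd.DataFrame:
        return self.scores.groupby("condition")[["r", "ccc"]].mean()


@dataclass
class DiscriminabilityResult:
    ranking: np.ndarray             # electrodes, most discriminable first
    selected: list                  # per-fold selected electrode indices
    accuracy: float
    kappa: float
    separation_scores: np.ndarray = field(default=None)  # type: ignore[assignment]


def blocked_kfold(n_trials: int, k: int) -> np.ndarray:
    """Assign ``n_trials`` consecutive trials to ``k`` contiguous blocks.

    Block sizes differ by at most one (the first ``n % k`` blocks get the
    extra trial).  Returns the fold index of every trial.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n_trials < k:
        raise ValidationError(f"cannot split {n_trials} trials into {k} folds")
    sizes = np.full(k, n_trials // k)
    sizes[: n_trials % k] += 1
    return np.repeat(np.arange(k), sizes)


def _check_series(a, b):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("series must have equal length >= 2")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValidationError("zero variance series: correlation undefined")
    return a, b


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation; raises on zero-variance input."""
    a, b = _check_series(a, b)
    am, bm = a - a.mean(), b - b.mean()
    return float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))


def ccc(a, b) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(a,b) / (var a + var b + (mean a - mean b)^2); equals r only
    when the two series share mean and variance, and |CCC| <= |r| always.
    """
    a, b = _check_series(a, b)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(2 * cov / (a.var() + b.var() + (a.mean() - b.mean()) ** 2))


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    from sklearn.metrics import cohen_kappa_score

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label arrays must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValidationError("need at least 2 classes in y_true")
    # degenerate marginals: chance agreement is 1 when both sides are constant
    classes = np.unique(np.concatenate([y_true, y_pred]))
    p_true = np.array([(y_true == c).mean() for c in classes])
    p_pred = np.array([(y_pred == c).mean() for c in classes])
    if float(p_true @ p_pred) >= 1.0:
        raise ValidationError("degenerate marginals: expected agreement is 1")
    return float(cohen_kappa_score(y_true, y_pred))


def cross_validate(x: FeatureTensor, y: TargetSet, labels, k: int = 5,
                   eps_rel: float = 1e-8, window: str = "hamming",
                   return_models: bool = False):
    """Blocked k-fold CV of the spectro-spatial decoder, per condition.

    Within each condition the trials are split into ``k`` contiguous blocks;
    each block is the test set exactly once while the others train the full
    model (filters + weights).  Scores (r, CCC) are computed per test trial
    and reported unaggregated; use :meth:`CvResult.mean_r` etc. to average.

    With ``return_models=True`` also returns ``{(condition, fold): model}``
    for downstream weight analyses.
    """
    from . import decoder

    labels = np.asarray([str(l) for l in labels])
    if len(labels) != x.n_trials:
        raise ValidationError("labels/trial count mismatch")
    rows, folds, models = [], {}, {}
    for cond in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == cond)
        fold_of = blocked_kfold(len(idx), k)
        folds[cond] = fold_of
        for f in range(k):
            train = idx[fold_of != f]
            test = idx[fold_of == f]
            if len(train) < 2:
                raise ValidationError(
                    f"condition {cond!r}, fold {f}: fewer than 2 training trials")
            model = decoder.fit(x.select_trials(train), y.select_trials(train),
                                eps_rel=eps_rel, condition=cond, window=window)
            pred = decoder.predict(model, x.select_trials(test))
            if return_models:
                models[(cond, f)] = model
            for ti, trial in enumerate(test):
                rows.append({
                    "condition": cond, "fold": f, "trial": int(trial),
                    "r": pearson_r(y.data[trial], pred.data[ti]),
                    "ccc": ccc(y.data[trial], pred.data[ti]),
                })
    result = CvResult(scores=pd.DataFrame(rows), folds=folds, k=k)
    return (result, models) if return_models else result


# ---------------------------------------------------------------------------
# Spatial-weight discriminability
# ---------------------------------------------------------------------------

def separation_score(values: np.ndarray, k_clusters: int, seed: int = 0) -> float:
    """Between-cluster / total sum of squares of 1-d K-means on ``values``."""
    from sklearn.cluster import KMeans

    values = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    if len(values) < k_clusters:
        raise ValidationError(
            f"need at least {k_clusters} observations, got {len(values)}")
    total = float(np.sum((values - values.mean()) ** 2))
    if total <= 0:
        return 0.0
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed).fit(values)
    return max(0.0, 1.0 - km.inertia_ / total)


def rank_electrodes(weights: np.ndarray, k_clusters: int, seed: int = 0):
    """Rank electrodes by the condition-separability of their coefficients.

    ``weights`` has shape (n_observations, n_electrodes) where observations
    are (condition, fold) weight magnitudes.  Each electrode's observations
    are clustered (1-d K-means, ``k_clusters`` groups, 10 restarts) and
    scored by between-cluster over total sum of squares; electrodes are
    ranked by descending score, ties broken by electrode index.

    Returns ``(ranking, scores)``.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 2:
        raise ValidationError("weights must be (observations, electrodes)")
    scores = np.array([separation_score(weights[:, j], k_clusters, seed)
                       for j in range(weights.shape[1])])
    ranking = np.lexsort((np.arange(len(scores)), -scores))
    return ranking, scores


def lda_discriminability(weights: np.ndarray, conditions, n_selected: int = 2,
                         k_clusters: int | None = None, k: int = 5,
                         fold_ids=None, seed: int = 0) -> DiscriminabilityResult:
    """Classify weight vectors by condition with LDA on top-ranked electrodes.

    Observations are per-(condition, fold) weight vectors.  Cross-validation
    reuses the fold structure: for each held-out fold, electrodes are ranked
    on the training folds only (no selection leakage), the best
    ``n_selected`` feed an LDA, and the held-out fold's vectors are
    classified.  ``n_selected=None`` uses all electrodes.

    Returns accuracy, Cohen's kappa, the full-data ranking (for reporting)
    and the per-fold selections actually used.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    weights = np.asarray(weights, dtype=np.float64)
    conditions = np.asarray([str(c) for c in conditions])
    n_obs, n_el = weights.shape
    if len(conditions) != n_obs:
        raise ValidationError("conditions/observations mismatch")
    if n_selected is not None and n_selected > n_el:
        raise ValidationError("n_selected exceeds number of electrodes")
    if k_clusters is None:
        k_clusters = len(np.unique(conditions))
    if fold_ids is None:
        # default: observations grouped per condition in order, one per fold
        fold_ids = np.concatenate(
            [np.arange(np.sum(conditions == c)) % k for c in dict.fromkeys(conditions.tolist())]
        )
    fold_ids = np.asarray(fold_ids)

    y_true, y_pred, selected = [], [], []
    for f in np.unique(fold_ids):
        train = fold_ids != f
        test = ~train
        if len(np.unique(conditions[train])) < len(np.unique(conditions)):
            raise ValidationError(f"fold {f}: a class is absent from training data")
        if n_selected is None:
            cols = np.arange(n_el)
        else:
            ranking, _ = rank_electrodes(weights[train], k_clusters, seed)
            cols = np.sort(ranking[:n_selected])
        selected.append(cols)
        lda = LinearDiscriminantAnalysis()
        lda.fit(weights[np.ix_(train, cols)], conditions[train])
        y_true.extend(conditions[test])
        y_pred.extend(lda.predict(weights[np.ix_(test, cols)]))

    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = float(np.mean(y_true == y_pred))
    try:
        kappa = cohen_kappa(y_true, y_pred)
    except ValidationError:
        kappa = 0.0
    full_ranking, scores = rank_electrodes(weights, k_clusters, seed)
    return DiscriminabilityResult(ranking=full_ranking, selected=selected,
                                  accuracy=acc, kappa=kappa,
                                  separation_scores=scores)


def weight_matrix(models: dict, magnitude: bool = True):
    """Stack per-(condition, fold) model weights into an observation matrix.

    ``models`` maps (condition, fold) -> DecodingModel (as returned by
    :func:`cross_validate` with ``return_models=True``).  Returns
    ``(W, conditions, fold_ids)`` with W of shape (n_obs, n_features).
    """
    keys = sorted(models.keys(), key=lambda t: (str(t[0]), t[1]))
    W = np.stack([models[k].weights.b for k in keys])
    if magnitude:
        W = np.abs(W)
    conds = np.array([str(k[0]) for k in keys])
    fold_ids = np.array([k[1] for k in keys])
    return W, conds, fold_ids
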