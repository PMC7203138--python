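"""Ridge-regularized temporal response function (mTRF) baseline.

The classic alternative to the coherence filter: expand the feature set with
lagged copies (here -500 ms to +500 ms in steps of one sample at the
analysis rate), regress the target on the expansion with an L2 penalty, and
pick the penalty strength lambda by nested cross-validation on the training
block.  The lambda grid is geometric, lambda_n = lambda_0 * ratio^n with
lambda_0 = 1e-6, ratio = 1.848 and 54 steps, spanning 1e-6 to ~1.4e8.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import TargetSet, ValidationError
from .evaluation import CvResult, blocked_kfold, ccc, pearson_r
from .preprocess import FeatureTensor

__all__ = [
    "LagConfig",
    "RidgeGrid",
    "lambda_grid",
    "build_lag_matrix",
    "ridge_fit",
    "nested_cv_mtrf",
]

logger = logging.getLogger(__name__)


@dataclass
class LagConfig:
    """Lag window in seconds; negative lags look into the future of x."""

    lag_min: float = -0.5
    lag_max: float = 0.5
    step: float | None = None     # defaults to 1/fs at build time

    def __post_init__(self) -> None:
        if not (self.lag_min <= 0 <= self.lag_max):
            raise ValidationError("lag window must contain 0")
        if self.step is not None and self.step <= 0:
            raise ValidationError("lag step must be positive")

    def lags_samples(self, fs: float) -> np.ndarray:
        step = self.step if self.step is not None else 1.0 / fs
        step_n = step * fs
        if abs(step_n - round(step_n)) > 1e-9 or round(step_n) < 1:
            raise ValidationError(
                f"lag step {step}s is not a whole number of samples at {fs} Hz")
        step_n = int(round(step_n))
        lo = int(round(self.lag_min * fs))
        hi = int(round(self.lag_max * fs))
        return np.arange(lo, hi + 1, step_n)


@dataclass
class RidgeGrid:
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=np.float64)
        if self.lambdas.size < 1 or np.any(self.lambdas <= 0):
            raise ValidationError("lambdas must be positive")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValidationError("lambdas must be strictly increasing")


def lambda_grid(lambda0: float = 1e-6, ratio: float = 1.848, n_steps: int = 54,
                spacing: str = "geometric") -> RidgeGrid:
    """Penalty grid lambda_n = lambda_0 * ratio^n, n = 0..n_steps-1.

    The default geometric progression spans 1e-6 to about 1.4e8 in 54
    logarithmically spaced steps.  ``spacing="linear"`` gives the literal
    reading lambda_0 * ratio * n (with the n = 0 term kept at lambda_0),
    provided for auditability only -- it never leaves the order of 1e-4.
    """
    if lambda0 <= 0 or n_steps < 1 or ratio <= 1:
        raise ValidationError("require lambda0 > 0, ratio > 1, n_steps >= 1")
    n = np.arange(n_steps)
    if spacing == "geometric":
        lams = lambda0 * ratio ** n
    elif spacing == "linear":
        lams = lambda0 * np.maximum(ratio * n, 1.0)
    else:
        raise ValidationError(f"unknown spacing {spacing!r}")
    return RidgeGrid(lambdas=lams)


def build_lag_matrix(x: FeatureTensor, cfg: LagConfig | None = None) -> np.ndarray:
    """Lag-expanded design matrix, trials concatenated row-wise.

    Each feature is shifted by every lag in the closed window; shifts are
    zero-padded at the trial edges so no samples leak between trials.  A
    positive lag ell places x(t - ell) in the row for time t.  Column order
    is feature-major: all lags of feature 0, then feature 1, ...

    Returns shape (n_trials * n_samples, n_features * n_lags).
    """
    cfg = cfg or LagConfig()
    lags = cfg.lags_samples(x.fs)
    K, J, T = x.data.shape
    if T <= len(lags):
        raise ValidationError("trial length must exceed the number of lags")
    X = np.zeros((K, T, J, len(lags)))
    for li, ell in enumerate(lags):
        if ell >= 0:
            X[:, ell:, :, li] = x.data.transpose(0, 2, 1)[:, : T - ell if ell else T, :]
        else:
            X[:, :ell, :, li] = x.data.transpose(0, 2, 1)[:, -ell:, :]
    return X.reshape(K * T, J * len(lags))


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float):
    """Ridge solution of (X'X + lam I) beta = X'y with an unpenalized intercept.

    Columns of X and y are centered so the intercept is excluded from the
    penalty; at lam = 0 a singular problem falls back to the minimum-norm
    least-squares solution with a logged warning.

    Returns ``(beta, intercept)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X rows and y length differ")
    if lam < 0:
        raise ValidationError("lam must be non-negative")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc, yc = X - xm, y - ym
    if lam == 0:
        G = Xc.T @ Xc
        if np.linalg.matrix_rank(G) < G.shape[0]:
            logger.warning("singular X'X at lam=0: using minimum-norm solution")
            beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        else:
            beta = np.linalg.solve(G, Xc.T @ yc)
    else:
        n_col = X.shape[1]
        beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(n_col), Xc.T @ yc)
    return beta, float(ym - xm @ beta)


def _ridge_path(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Solve the full ridge path cheaply via one SVD of the centered design."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    # beta(lam) = V diag(s/(s^2+lam)) U'y
    shrink = s[np.newaxis, :] / (s[np.newaxis, :] ** 2 + lambdas[:, np.newaxis])
    return (shrink * Uty[np.newaxis, :]) @ Vt


def nested_cv_mtrf(x: FeatureTensor, y: TargetSet, labels,
                   grid: RidgeGrid | None = None, cfg: LagConfig | None = None,
                   k_outer: int = 5, k_inner: int = 4) -> CvResult:
    """Nested blocked CV of the lagged ridge baseline, per condition.

    For each outer training block an inner blocked CV picks the lambda with
    the best mean inner-fold r; the model is refit on the whole outer
    training block at that lambda and scored per held-out trial (r, CCC),
    matching the fold geometry and scoring of the primary method.
    """
    grid = grid or lambda_grid()
    cfg = cfg or LagConfig()
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != x.n_trials:
        raise ValidationError("labels/trial count mismatch")
    T = x.n_samples
    rows, folds, chosen = [], {}, {}
    for cond in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == cond)
        fold_of = blocked_kfold(len(idx), k_outer)
        folds[cond] = fold_of
        for f in range(k_outer):
            tr = idx[fold_of != f]
            te = idx[fold_of == f]
            lam = _select_lambda(x, y, tr, grid, cfg, k_inner)
            chosen[(cond, f)] = lam
            Xtr = build_lag_matrix(x.select_trials(tr), cfg)
            beta, b0 = ridge_fit(Xtr, y.data[tr].ravel(), lam)
            Xte = build_lag_matrix(x.select_trials(te), cfg)
            pred = (Xte @ beta + b0).reshape(len(te), T)
            for ti, trial in enumerate(te):
                rows.append({
                    "condition": cond, "fold": f, "trial": int(trial),
                    "r": pearson_r(y.data[trial], pred[ti]),
                    "ccc": ccc(y.data[trial], pred[ti]),
                    "lam": lam,
                })
    return CvResult(scores=pd.DataFrame(rows), folds=folds, k=k_outer)


def _select_lambda(x: FeatureTensor, y: TargetSet, train_idx, grid: RidgeGrid,
                   cfg: LagConfig, k_inner: int) -> float:
    """Inner blocked CV over the grid; returns the lambda with best mean r."""
    if len(grid.lambdas) == 1:
        return float(grid.lambdas[0])
    T = x.n_samples
    inner = blocked_kfold(len(train_idx), min(k_inner, len(train_idx)))
    mean_r = np.zeros(len(grid.lambdas))
    n_scored = 0
    for g in range(inner.max() + 1):
        tr = train_idx[inner != g]
        te = train_idx[inner == g]
        if len(tr) < 2:
            continue
        Xtr = build_lag_matrix(x.select_trials(tr), cfg)
        ytr = y.data[tr].ravel()
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        betas = _ridge_path(Xtr - xm, ytr - ym, grid.lambdas)   # (L, P)
        Xte = build_lag_matrix(x.select_trials(te), cfg)
        preds = (Xte - xm) @ betas.T + ym                        # (rows, L)
        yte = y.data[te].ravel()
        for li in range(len(grid.lambdas)):
            p = preds[:, li].reshape(len(te), T)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rs = []
                for ti in range(len(te)):
                    if np.var(p[ti]) == 0:
                        rs.append(0.0)
                    else:
                        rs.append(pearson_r(y.data[te[ti]], p[ti]))
            mean_r[li] += float(np.mean(rs))
        n_scored += 1
    mean_r /= max(n_scored, 1)
    return float(grid.lambdas[int(np.argmax(mean_r))])
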