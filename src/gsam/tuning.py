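"""Regularization paths and K-fold cross-validation.

The path starts at the smallest penalty level that produces the null
model.  With an unpenalized intercept the relevant soft-scaling threshold
is the *centered* response norm ``||y - ybar||_n`` (this coincides with
``||y||_n`` whenever ybar = 0); for binomial and poisson losses the score
at the null intercept is again ``y - ybar``, so the same formula applies
on the link scale.  Path values are log-linear down to
``lambda_max * min_ratio``.

Cross-validation selects lambda by held-out mean squared prediction error
(gaussian) or by held-out AUC (binomial, larger is better), with the
usual one-standard-error rule available: the largest lambda whose mean
criterion is within one SE of the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .losses import LossSpec
from .solver import AdditiveModel, FitConfig, block_cd_fit, fit, predict, _as_penalty_list, _make_designs

__all__ = ["LambdaPath", "CVResult", "lambda_max", "make_path", "fit_path", "kfold_cv"]


@dataclass(frozen=True)
class LambdaPath:
    """Strictly decreasing, log-linearly spaced penalty levels."""

    values: np.ndarray
    lambda_max: float
    n_lambda: int
    min_ratio: float


def lambda_max(y: np.ndarray, X: Optional[np.ndarray] = None, loss: LossSpec = LossSpec("gaussian")) -> float:
    """Smallest penalty level at which the fit is the null model."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need n >= 2")
    val = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    if val == 0.0:
        warnings.warn(
            "constant response: lambda_max is 0 and the path degenerates to the null model",
            RuntimeWarning,
            stacklevel=2,
        )
    return val


def make_path(lam_max: float, n_lambda: int = 50, min_ratio: float = 1e-3) -> LambdaPath:
    """Geometric sequence from lam_max down to lam_max * min_ratio."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    if n_lambda == 1:
        values = np.array([lam_max])
    else:
        values = np.geomspace(lam_max, lam_max * min_ratio, n_lambda)
    return LambdaPath(values=values, lambda_max=lam_max, n_lambda=n_lambda, min_ratio=min_ratio)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    path: LambdaPath,
    penalties,
    loss: LossSpec = LossSpec("gaussian"),
    config: Optional[FitConfig] = None,
    use_cd: Optional[bool] = None,
) -> list[AdditiveModel]:
    """Warm-started fits along the decreasing lambda path.

    Gaussian fits default to block coordinate descent; other losses use
    proximal gradient descent.
    """
    config = config or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if use_cd is None:
        use_cd = loss.family == "gaussian"
    p = X.shape[1]
    pen_list = _as_penalty_list(penalties, p)
    designs = _make_designs(X, pen_list)
    models = []
    init = None
    for lam in path.values:
        if use_cd:
            m = block_cd_fit(X, y, lam, pen_list, config=config, init=init, designs=designs)
        else:
            m = fit(X, y, lam, pen_list, loss=loss, config=config, init=init, designs=designs)
        models.append(m)
        F = np.column_stack(
            [np.interp(X[:, j], xk, vk) for j, (xk, vk) in enumerate(m.knots)]
        )
        init = (m.beta, F)
    return models


@dataclass
class CVResult:
    """Cross-validation curve and the selected penalty levels."""

    lambdas: np.ndarray
    mean: np.ndarray  # mean validation criterion per lambda (smaller is better)
    se: np.ndarray
    lambda_min: float
    lambda_1se: float
    criterion: str
    seed: int
    fold_sizes: list = field(default_factory=list)


def _fold_assignment(y: np.ndarray, K: int, seed: int, stratify: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = y.size
    folds = np.empty(n, dtype=int)
    if stratify:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(idx.size) % K
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % K
    return folds


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    path: LambdaPath,
    penalties,
    loss: LossSpec = LossSpec("gaussian"),
    K: int = 5,
    config: Optional[FitConfig] = None,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validation over a warm-started lambda path.

    Gaussian: held-out mean squared prediction error.  Binomial: held-out
    AUC, selecting the *largest* validation AUC (stored internally as
    -AUC so that smaller is uniformly better); folds are stratified by
    response.  Fold assignment is deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if K < 2 or n < 2 * K:
        raise ValueError("need K >= 2 folds and n >= 2K samples")
    binom = loss.family == "binomial"
    folds = _fold_assignment(y, K, seed, stratify=binom)
    n_lam = path.values.size
    crit = np.full((K, n_lam), np.nan)
    for k in range(K):
        tr, va = folds != k, folds == k
        if binom and np.unique(y[va]).size < 2:
            warnings.warn(
                f"fold {k}: held-out response is constant, AUC undefined; fold excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        models = fit_path(X[tr], y[tr], path, penalties, loss=loss, config=config)
        for i, m in enumerate(models):
            pred = predict(m, X[va])
            if binom:
                from sklearn.metrics import roc_auc_score

                crit[k, i] = -roc_auc_score(y[va], pred["response"])
            else:
                crit[k, i] = np.mean((y[va] - pred["link"]) ** 2)
    used = ~np.all(np.isnan(crit), axis=1)
    crit = crit[used]
    k_used = crit.shape[0]
    mean = crit.mean(axis=0)
    se = crit.std(axis=0, ddof=1) / np.sqrt(k_used) if k_used > 1 else np.zeros(n_lam)
    best = int(np.nanargmin(mean))
    lam_min = float(path.values[best])
    within = np.flatnonzero(mean <= mean[best] + se[best])
    lam_1se = float(path.values[within.min()])  # path is decreasing: first index = largest lambda
    return CVResult(
        lambdas=path.values.copy(),
        mean=mean,
        se=se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        criterion="auc" if binom else "mse",
        seed=seed,
        fold_sizes=[int(np.sum(folds == k)) for k in range(K)],
    )
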