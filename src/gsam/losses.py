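"""Exponential-family loss functions for additive-model fitting.

Each loss is the negative log-likelihood ``-l(y, theta)`` of an
exponential-family distribution, viewed as a function of the linear
predictor ``theta`` on the link scale.  The proximal-gradient solver needs
three things from a loss: the empirical mean of ``-l``, the score vector
``l_dot`` (derivative of the *log-likelihood*, i.e. the ascent direction),
and a global curvature bound ``L >= |l_ddot|`` used to set step sizes.

Conventions
-----------
gaussian
    ``-l(y, theta) = (y - theta)^2 / 2``.  The 1/2 scaling makes the
    curvature bound exactly 1 and the proximal step algebra clean; it only
    rescales the regularization path relative to the unscaled squared
    error.
binomial
    canonical logit link, ``-l = -(y*theta - log(1 + e^theta))`` with
    ``y in {0, 1}``; curvature bound 1/4.
poisson
    canonical log link, ``-l = -(y*theta - e^theta)`` (the ``log y!`` term
    is dropped as a constant); the second derivative ``-e^theta`` is
    unbounded, so step sizes must come from backtracking.  Linear
    predictors are clipped to ``|theta| <= 30`` to avoid overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossSpec",
    "neg_loglik",
    "neg_loglik_grad",
    "curvature_bound",
    "inverse_link",
]

_FAMILIES = ("gaussian", "binomial", "poisson")
_THETA_CLIP = 30.0


@dataclass(frozen=True)
class LossSpec:
    """An exponential-family loss identified by its family name.

    ``curvature_bound`` is the global bound L on ``|l_ddot|``; it is
    ``math.inf`` for families without one (poisson), which forces the
    solver onto backtracking line search.
    """

    family: str = "gaussian"
    curvature_bound: float = field(init=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown loss family {self.family!r}; choose from {_FAMILIES}"
            )
        bound = {"gaussian": 1.0, "binomial": 0.25, "poisson": np.inf}[self.family]
        object.__setattr__(self, "curvature_bound", bound)


def _validate(y: np.ndarray, theta: np.ndarray, loss: LossSpec) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if y.shape != theta.shape or y.ndim != 1 or y.size < 1:
        raise ValueError(
            f"y and theta must be 1-d vectors of equal length, got {y.shape} and {theta.shape}"
        )
    if loss.family == "binomial":
        if not np.all((y == 0.0) | (y == 1.0)):
            raise ValueError("binomial response must lie in {0, 1}")
    elif loss.family == "poisson":
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("poisson response must be nonnegative integers")
        theta = np.clip(theta, -_THETA_CLIP, _THETA_CLIP)
    return y, theta


def neg_loglik(y: np.ndarray, theta: np.ndarray, loss: LossSpec) -> float:
    """Empirical mean of the negative log-likelihood, ``-P_n l(theta)``."""
    y, theta = _validate(y, theta, loss)
    if loss.family == "gaussian":
        return float(np.mean((y - theta) ** 2) / 2.0)
    if loss.family == "binomial":
        # log(1 + e^t) computed stably for large |t|
        return float(np.mean(np.logaddexp(0.0, theta) - y * theta))
    return float(np.mean(np.exp(theta) - y * theta))


def neg_loglik_grad(y: np.ndarray, theta: np.ndarray, loss: LossSpec) -> np.ndarray:
    """Score vector ``l_dot(y_i, theta_i)`` (gradient of the log-likelihood).

    Note the sign: this is the *ascent* direction of the likelihood, so the
    solver's update ``f + t * l_dot`` moves downhill on ``-P_n l``.
    """
    y, theta = _validate(y, theta, loss)
    if loss.family == "gaussian":
        return y - theta
    if loss.family == "binomial":
        from scipy.special import expit

        return y - expit(theta)
    return y - np.exp(theta)


def curvature_bound(loss: LossSpec) -> float:
    """Global bound on ``|l_ddot|``; ``inf`` means no finite bound exists."""
    return loss.curvature_bound


def inverse_link(theta: np.ndarray, loss: LossSpec) -> np.ndarray:
    """Map the linear predictor to the response (mean) scale."""
    theta = np.asarray(theta, dtype=float)
    if loss.family == "gaussian":
        return theta
    if loss.family == "binomial":
        from scipy.special import expit

        return expit(theta)
    return np.exp(np.clip(theta, -_THETA_CLIP, _THETA_CLIP))
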