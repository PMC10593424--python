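"""Outer optimization for sparse additive models.

Fits g(E[y|x]) = beta + sum_j f_j(x_j) by accelerated proximal gradient
descent: each iteration takes a gradient step on the loss and then solves,
independently per feature, the univariate structure + sparsity subproblem
of :mod:`gsam.penalties`.  Step sizes come from the curvature bound L of
the loss (fixed t = 1/((p+1)L), an active-set-adaptive variant, or
backtracking when L is unbounded), and every accepted step satisfies the
quadratic majorization inequality, so the objective trace is
non-increasing.  For squared loss a block coordinate descent variant is
provided which needs no step size at all.

Penalty weights follow the coupled rule (w1, w2) = (lambda^2, lambda) by
default; setting ``zeta`` in [0, 1] switches to the two-parameter form
((1 - zeta) * lambda, zeta * lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .losses import LossSpec, curvature_bound, inverse_link, neg_loglik, neg_loglik_grad
from .penalties import (
    FeatureDesign,
    PenaltySpec,
    ProxProblem,
    emp_norm,
    penalty_value,
    prox_univariate,
)

__all__ = [
    "FitConfig",
    "FitState",
    "AdditiveModel",
    "objective",
    "prox_gradient_iteration",
    "step_size",
    "check_majorization",
    "fit",
    "block_cd_fit",
    "predict",
]


@dataclass
class FitConfig:
    """Solver settings; defaults suit path fitting on standardized data."""

    max_iter: int = 2000
    rel_tol: float = 1e-7
    step_policy: str = "fixed"  # fixed | active_set | backtracking
    accelerate: bool = True
    zeta: Union[str, float] = "coupled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.step_policy not in ("fixed", "active_set", "backtracking"):
            raise ValueError(f"unknown step policy {self.step_policy!r}")
        if self.zeta != "coupled" and not (0.0 <= float(self.zeta) <= 1.0):
            raise ValueError("zeta must be 'coupled' or a scalar in [0, 1]")

    def weights(self, lam: float) -> tuple[float, float]:
        """(structure weight w1, sparsity weight w2) for penalty level lam."""
        if self.zeta == "coupled":
            return lam * lam, lam
        z = float(self.zeta)
        return (1.0 - z) * lam, z * lam


@dataclass
class FitState:
    """Solver internals at one iteration."""

    beta: float
    F: np.ndarray  # n x p component values
    t: float
    objective: float
    iter: int = 0
    momentum_beta: float = 0.0
    momentum_F: Optional[np.ndarray] = None


@dataclass
class AdditiveModel:
    """A fitted sparse additive model.

    Component functions are stored as sorted (x, f(x)) knot tables; they
    are evaluated off-sample by piecewise-linear interpolation with
    constant extrapolation beyond the training range.
    """

    beta: float
    knots: list  # per feature: (x_knots ascending, values)
    active_set: list
    lam: float
    penalties: list
    loss: LossSpec
    zeta: Union[str, float] = "coupled"
    converged: bool = True
    n_iter: int = 0
    objective_value: float = np.nan
    objective_trace: list = None

    @property
    def p(self) -> int:
        return len(self.knots)


def _as_penalty_list(penalties, p: int) -> list[PenaltySpec]:
    if isinstance(penalties, PenaltySpec):
        return [penalties] * p
    penalties = list(penalties)
    if len(penalties) != p:
        raise ValueError(f"expected {p} penalty specs, got {len(penalties)}")
    return penalties


def _make_designs(X: np.ndarray, penalties: list[PenaltySpec]) -> list[FeatureDesign]:
    return [FeatureDesign(X[:, j], penalties[j]) for j in range(X.shape[1])]


def objective(
    beta: float,
    F: np.ndarray,
    y: np.ndarray,
    designs: Sequence[FeatureDesign],
    loss: LossSpec,
    w1: float,
    w2: float,
) -> float:
    """Penalized objective -P_n l + w1 * sum Pst(f_j) + w2 * sum ||f_j||_n.

    Indicator-penalty violations make the objective +inf by convention.
    """
    theta = beta + F.sum(axis=1)
    val = neg_loglik(y, theta, loss)
    for j, d in enumerate(designs):
        pv = penalty_value(F[:, j], d)
        if not np.isfinite(pv):
            return np.inf
        val += w1 * pv + w2 * emp_norm(F[:, j])
    return float(val)


def step_size(
    loss: LossSpec,
    policy: str,
    p: int,
    p_active: int = 0,
    t_current: float = 1.0,
) -> float:
    """Step size t for one proximal-gradient iteration."""
    L = curvature_bound(loss)
    if policy in ("fixed", "active_set") and not np.isfinite(L):
        raise ValueError(
            f"loss family {loss.family!r} has no finite curvature bound; "
            "use step_policy='backtracking'"
        )
    if policy == "fixed":
        return 1.0 / ((p + 1) * L)
    if policy == "active_set":
        return 1.0 / (L * (p_active + 1))
    return t_current


def check_majorization(
    beta0: float,
    F0: np.ndarray,
    beta1: float,
    F1: np.ndarray,
    t: float,
    y: np.ndarray,
    loss: LossSpec,
) -> bool:
    """True iff -P_n l at the new state sits below the quadratic surrogate
    at the old state with curvature 1/t."""
    theta0 = beta0 + F0.sum(axis=1)
    theta1 = beta1 + F1.sum(axis=1)
    g = neg_loglik_grad(y, theta0, loss)
    db = beta1 - beta0
    lin = -db * g.mean() - np.mean((F1 - F0) * g[:, None], axis=0).sum()
    quad = (db * db + np.mean((F1 - F0) ** 2, axis=0).sum()) / (2.0 * t)
    lhs = neg_loglik(y, theta1, loss)
    rhs = neg_loglik(y, theta0, loss) + lin + quad
    return bool(lhs <= rhs + 1e-12 * max(1.0, abs(rhs)))


def prox_gradient_iteration(
    beta0: float,
    F0: np.ndarray,
    y: np.ndarray,
    designs: Sequence[FeatureDesign],
    penalties: Sequence[PenaltySpec],
    loss: LossSpec,
    t: float,
    w1: float,
    w2: float,
    warm_lt: Optional[list] = None,
) -> tuple[float, np.ndarray]:
    """One majorize-minimize step: intercept update + per-feature prox.

    Component updates are independent of each other (they could run in
    parallel); each solves the univariate subproblem on the centered
    gradient-step target with weights (t*w1, t*w2).
    """
    theta0 = beta0 + F0.sum(axis=1)
    g = neg_loglik_grad(y, theta0, loss)
    beta1 = beta0 + t * g.mean()
    F1 = np.empty_like(F0)
    for j in range(F0.shape[1]):
        r = F0[:, j] + t * g
        r = r - r.mean()
        prob = ProxProblem(r, designs[j].x, t * w1, t * w2, design=designs[j])
        fit_j = prox_univariate(
            prob, penalties[j], lambda_tilde_init=None if warm_lt is None else warm_lt[j]
        )
        if warm_lt is not None:
            warm_lt[j] = fit_j.lambda_tilde
        F1[:, j] = fit_j.values
    return beta1, F1


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalties,
    loss: LossSpec = LossSpec("gaussian"),
    config: Optional[FitConfig] = None,
    init: Optional[tuple[float, np.ndarray]] = None,
    designs: Optional[list] = None,
) -> AdditiveModel:
    """Fit one sparse additive model at penalty level ``lam``.

    ``init`` allows warm starts along a regularization path; ``designs``
    allows reuse of per-feature precomputations across path points.
    """
    config = config or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with n matching len(y)")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 samples and p >= 1 features")
    penalties = _as_penalty_list(penalties, p)
    if designs is None:
        designs = _make_designs(X, penalties)
    w1, w2 = config.weights(lam)

    if init is not None:
        beta, F = float(init[0]), np.array(init[1], dtype=float, copy=True)
    else:
        beta, F = 0.0, np.zeros((n, p))
    obj = objective(beta, F, y, designs, loss, w1, w2)
    trace = [obj]
    warm_lt: list = [None] * p
    L = curvature_bound(loss)
    t = step_size(loss, config.step_policy, p) if config.step_policy != "backtracking" else 1.0

    # FISTA bookkeeping
    a_k = 1.0
    beta_prev, F_prev = beta, F.copy()
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        if config.accelerate:
            mom = (a_k - 1.0) / (0.5 * (1.0 + np.sqrt(1.0 + 4.0 * a_k * a_k)))
            beta_v = beta + mom * (beta - beta_prev)
            F_v = F + mom * (F - F_prev)
        else:
            beta_v, F_v = beta, F

        def propose(b0, G0, step):
            return prox_gradient_iteration(
                b0, G0, y, designs, penalties, loss, step, w1, w2, warm_lt
            )

        if config.step_policy == "active_set":
            p_act = int(np.count_nonzero(np.abs(F_v).max(axis=0) > 0))
            t = step_size(loss, "active_set", p, p_act)
            beta_n, F_n = propose(beta_v, F_v, t)
            p_union = int(
                np.count_nonzero(
                    (np.abs(F_v).max(axis=0) > 0) | (np.abs(F_n).max(axis=0) > 0)
                )
            )
            if p_union > p_act:
                t = step_size(loss, "active_set", p, p_union)
                beta_n, F_n = propose(beta_v, F_v, t)
        elif config.step_policy == "backtracking":
            t = min(t * 2.0, 1e6)
            beta_n, F_n = propose(beta_v, F_v, t)
            for _ in range(60):
                if check_majorization(beta_v, F_v, beta_n, F_n, t, y, loss):
                    break
                t /= 2.0
                beta_n, F_n = propose(beta_v, F_v, t)
        else:
            beta_n, F_n = propose(beta_v, F_v, t)

        new_obj = objective(beta_n, F_n, y, designs, loss, w1, w2)
        if config.accelerate and new_obj > obj:
            # adaptive restart: momentum overshoots, redo a plain step
            a_k = 1.0
            beta_n, F_n = propose(beta, F, t)
            new_obj = objective(beta_n, F_n, y, designs, loss, w1, w2)
        if config.step_policy == "active_set":
            # the adaptive step is a heuristic; halve until descent holds
            for _ in range(60):
                if new_obj <= obj + 1e-12 * max(1.0, abs(obj)):
                    break
                t /= 2.0
                beta_n, F_n = propose(beta, F, t)
                new_obj = objective(beta_n, F_n, y, designs, loss, w1, w2)
        if new_obj > obj + 1e-12 * max(1.0, abs(obj)):
            # descent safeguard (should not trigger for valid step sizes)
            break
        beta_prev, F_prev = beta, F
        beta, F = beta_n, F_n
        trace.append(new_obj)
        a_k = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * a_k * a_k)) if config.accelerate else 1.0
        if abs(obj - new_obj) < config.rel_tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged and it >= config.max_iter:
        warnings.warn(
            f"proximal gradient did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return _build_model(beta, F, lam, penalties, loss, config, designs, converged, it, obj, trace)


def block_cd_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalties,
    config: Optional[FitConfig] = None,
    loss: LossSpec = LossSpec("gaussian"),
    init: Optional[tuple[float, np.ndarray]] = None,
    designs: Optional[list] = None,
) -> AdditiveModel:
    """Block coordinate descent for squared loss: cycle over features,
    solving each univariate subproblem on the full partial residual with
    weights (w1, w2) directly (no step size); intercept re-estimated each
    sweep."""
    if loss.family != "gaussian":
        raise ValueError("block coordinate descent supports the gaussian loss only")
    config = config or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    n, p = X.shape
    penalties = _as_penalty_list(penalties, p)
    if designs is None:
        designs = _make_designs(X, penalties)
    w1, w2 = config.weights(lam)

    if init is not None:
        beta, F = float(init[0]), np.array(init[1], dtype=float, copy=True)
    else:
        beta, F = float(y.mean()), np.zeros((n, p))
    res = y - beta - F.sum(axis=1)
    obj = objective(beta, F, y, designs, loss, w1, w2)
    trace = [obj]
    warm_lt: list = [None] * p
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        for j in range(p):
            r_j = res + F[:, j]
            r_c = r_j - r_j.mean()
            prob = ProxProblem(r_c, designs[j].x, w1, w2, design=designs[j])
            fit_j = prox_univariate(prob, penalties[j], lambda_tilde_init=warm_lt[j])
            warm_lt[j] = fit_j.lambda_tilde
            F[:, j] = fit_j.values
            res = r_j - F[:, j]
        shift = res.mean()
        beta += shift
        res -= shift
        new_obj = objective(beta, F, y, designs, loss, w1, w2)
        trace.append(new_obj)
        if abs(obj - new_obj) < config.rel_tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged and it >= config.max_iter:
        warnings.warn(
            f"block coordinate descent did not converge in {config.max_iter} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return _build_model(beta, F, lam, penalties, loss, config, designs, converged, it, obj, trace)


def _build_model(beta, F, lam, penalties, loss, config, designs, converged, n_iter, obj, trace=None):
    knots = []
    active = []
    for j, d in enumerate(designs):
        vals = d.collapse(F[:, j])
        knots.append((d.x_unique.copy(), vals))
        if emp_norm(F[:, j]) > 0.0:
            active.append(j)
    return AdditiveModel(
        beta=float(beta),
        knots=knots,
        active_set=active,
        lam=float(lam),
        penalties=list(penalties),
        loss=loss,
        zeta=config.zeta,
        converged=converged,
        n_iter=n_iter,
        objective_value=float(obj),
        objective_trace=list(trace) if trace is not None else None,
    )


def predict(model: AdditiveModel, X_new: np.ndarray) -> dict:
    """Evaluate the fitted additive surface at new points.

    Components are piecewise-linear between training knots and constant
    beyond the training range.  Returns the linear predictor (``link``)
    and the inverse-linked ``response``.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != model.p:
        raise ValueError(f"expected {model.p} columns, got {X_new.shape[1]}")
    link = np.full(X_new.shape[0], model.beta)
    for j, (xk, yk) in enumerate(model.knots):
        link += np.interp(X_new[:, j], xk, yk)
    return {"link": link, "response": inverse_link(link, model.loss)}
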