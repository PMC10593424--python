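"""Independent oracles for cross-checking the package's solvers.

These share no code with the package's optimization routines.  The main
tool is a generic convex minimizer: every nonsmooth term |z| (and the
empirical norm ||f||_n) is replaced by the smooth surrogate
sqrt(z^2 + eps^2), and the smoothed objective is minimized with L-BFGS-B
under eps-continuation.  All objectives here are strongly convex (the
squared-loss term), so the true objective at the smoothed minimizer is
within O(eps * total penalty weight) of the true minimum; the final eps
of 1e-9 puts that error far below the 1e-6 relative tolerance used in
comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear, minimize

_EPS_SCHEDULE = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9)


def _smooth_abs(z: np.ndarray, eps: float) -> np.ndarray:
    return np.sqrt(z * z + eps * eps)


def _smooth_abs_grad(z: np.ndarray, eps: float) -> np.ndarray:
    return z / np.sqrt(z * z + eps * eps)


def smoothed_minimize(fun_grad, x0: np.ndarray, bounds=None) -> np.ndarray:
    """Minimize fun_grad(x, eps) -> (value, grad) with eps-continuation.

    Within each continuation stage L-BFGS-B is restarted until it
    stagnates, which matters for stiff penalty operators (closely spaced
    knots make the difference operators badly conditioned).
    """
    x = np.asarray(x0, dtype=float).copy()
    for eps in _EPS_SCHEDULE:
        prev = np.inf
        for _ in range(8):
            res = minimize(
                lambda v: fun_grad(v, eps),
                x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 40000, "ftol": 1e-18, "gtol": 1e-14, "maxcor": 30},
            )
            x = res.x
            if prev - res.fun <= 1e-14 * (1.0 + abs(prev)):
                break
            prev = res.fun
    return x


def diff_operator(x_sorted: np.ndarray, k: int) -> np.ndarray:
    """Dense (k+1)-th order divided-difference penalty operator for TV_k.

    Row count n - k - 1; the l1 norm of the product with f is the
    discrete k-th order total variation on the grid x_sorted.
    """
    n = x_sorted.size
    D = np.eye(n)
    # scaled k-th divided difference
    for order in range(1, k + 1):
        m = D.shape[0]
        D1 = np.zeros((m - 1, m))
        idx = np.arange(m - 1)
        D1[idx, idx] = -1.0
        D1[idx, idx + 1] = 1.0
        span = x_sorted[order:] - x_sorted[:-order]
        D = order * (D1 @ D) / span[:, None]
    # final plain first difference turns D_k f into its jumps
    m = D.shape[0]
    D1 = np.zeros((m - 1, m))
    idx = np.arange(m - 1)
    D1[idx, idx] = -1.0
    D1[idx, idx + 1] = 1.0
    return D1 @ D


def sobolev_operator(x_sorted: np.ndarray) -> np.ndarray:
    """Quadrature-weighted second divided-difference operator (dense)."""
    n = x_sorted.size
    if n < 3:
        return np.zeros((0, n))
    h = np.diff(x_sorted)
    span = x_sorted[2:] - x_sorted[:-2]
    q = np.sqrt(span / 2.0)
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    c0 = 2.0 / (h[:-1] * span)
    c2 = 2.0 / (h[1:] * span)
    D[idx, idx] = q * c0
    D[idx, idx + 1] = -q * (c0 + c2)
    D[idx, idx + 2] = q * c2
    return D


def univariate_objective(f, r, kind, lam1, lam2, D=None, q=1, weights=None):
    """True (unsmoothed) structure+sparsity objective on the fitting grid.

    ``weights`` are point multiplicities when the grid is tie-collapsed;
    the normalizer is the total sample count sum(weights).
    """
    w = np.ones(r.size) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()
    val = 0.5 * np.sum(w * (r - f) ** 2) / n + lam2 * np.sqrt(np.sum(w * f**2) / n)
    if D is not None and D.shape[0]:
        z = D @ f
        val += lam1 * (np.sum(np.abs(z)) if q == 1 else np.linalg.norm(z))
    return float(val)


def solve_univariate(r, x_sorted, kind, lam1, lam2, k=0, basis=None, weights=None):
    """Generic convex solve of the univariate subproblem, in sorted order.

    kind: 'tv' (order k), 'sobolev', 'subspace' (needs basis), 'monotone'.
    ``weights`` are point multiplicities on a tie-collapsed grid.
    Returns the fitted vector at the grid points.
    """
    r = np.asarray(r, dtype=float)
    w = np.ones(r.size) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()

    if kind == "subspace":
        B = np.asarray(basis, dtype=float)
        B = B - B.mean(axis=0)

        def fg(c, eps):
            f = B @ c
            resid = f - r
            nf = np.sqrt(np.sum(w * f**2) / n + eps * eps)
            val = 0.5 * np.sum(w * resid**2) / n + lam2 * nf
            grad_f = w * resid / n + lam2 * w * f / (n * nf)
            return val, B.T @ grad_f

        c = smoothed_minimize(fg, np.zeros(B.shape[1]))
        return B @ c

    if kind == "monotone":
        # f_i = a + cumsum(d), d >= 0; strongly convex in (a, d)
        def fg(v, eps):
            a, d = v[0], v[1:]
            f = a + np.concatenate([[0.0], np.cumsum(d)])
            resid = f - r
            nf = np.sqrt(np.sum(w * f**2) / n + eps * eps)
            val = 0.5 * np.sum(w * resid**2) / n + lam2 * nf
            gf = w * resid / n + lam2 * w * f / (n * nf)
            # chain rule through the cumulative parametrization
            ga = gf.sum()
            gd = np.cumsum(gf[::-1])[::-1][1:]
            return val, np.concatenate([[ga], gd])

        m = r.size
        bounds = [(None, None)] + [(0.0, None)] * (m - 1)
        v = smoothed_minimize(fg, np.zeros(m), bounds=bounds)
        return v[0] + np.concatenate([[0.0], np.cumsum(v[1:])])

    if kind == "tv":
        D = diff_operator(x_sorted, k)
        q = 1
    elif kind == "sobolev":
        D = sobolev_operator(x_sorted)
        q = 2
    else:
        raise ValueError(kind)

    # start in the penalty's null space (degree-k polynomial fit): the
    # smoothed objective is approached from the low-penalty side, which is
    # far better conditioned than starting at r when knots nearly coincide
    deg = k if kind == "tv" else 1
    V = np.vander(x_sorted, deg + 1)
    f_init = V @ np.linalg.lstsq(V, r, rcond=None)[0]

    def fg(f, eps):
        resid = f - r
        nf = np.sqrt(np.sum(w * f**2) / n + eps * eps)
        val = 0.5 * np.sum(w * resid**2) / n + lam2 * nf
        grad = w * resid / n + lam2 * w * f / (n * nf)
        if D.shape[0]:
            z = D @ f
            if q == 1:
                val += lam1 * np.sum(_smooth_abs(z, eps))
                grad = grad + lam1 * (D.T @ _smooth_abs_grad(z, eps))
            else:
                nz = np.sqrt(z @ z + eps * eps)
                val += lam1 * nz
                grad = grad + lam1 * (D.T @ z) / nz
        return val, grad

    return smoothed_minimize(fg, f_init)


def isotonic_qp(r, weights=None):
    """Monotone least squares via bound-constrained least squares.

    Parametrize f = a + cumsum of nonnegative increments and solve the
    resulting linear least-squares problem with scipy's lsq_linear.
    """
    r = np.asarray(r, dtype=float)
    n = r.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    # design: column 0 = intercept (free), columns 1.. = step increments
    A = np.tril(np.ones((n, n)))
    A[:, 0] = 1.0
    sw = np.sqrt(w)
    res = lsq_linear(
        A * sw[:, None],
        r * sw,
        bounds=(np.r_[-np.inf, np.zeros(n - 1)], np.full(n, np.inf)),
        tol=1e-14,
        max_iter=2000,
    )
    return A @ res.x


def lasso_cd(X, y, lam_weights, max_iter=20000, tol=1e-14):
    """Weighted lasso by plain cyclic coordinate descent (soft-thresholding).

    Minimizes 0.5*mean((y - b0 - X b)^2) + sum_j lam_weights[j] * |b_j|.
    Independent reference for the subspace-penalty special case.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    b = np.zeros(p)
    b0 = y.mean()
    r = y - b0 - X @ b
    col_ss = np.mean(X**2, axis=0)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = np.mean(X[:, j] * r) + col_ss[j] * old
            new = np.sign(rho) * max(abs(rho) - lam_weights[j], 0.0) / col_ss[j]
            if new != old:
                r += X[:, j] * (old - new)
                b[j] = new
                delta = max(delta, abs(old - new))
        shift = r.mean()
        b0 += shift
        r -= shift
        if delta < tol:
            break
    return b0, b


def additive_objective_tv0(beta, F, y, orders, lam, w1=None, w2=None):
    """Full additive objective with half-scaled gaussian loss and TV-0
    penalties, evaluated on arbitrary component values."""
    w1 = lam * lam if w1 is None else w1
    w2 = lam if w2 is None else w2
    theta = beta + F.sum(axis=1)
    val = 0.5 * np.mean((y - theta) ** 2)
    for j in range(F.shape[1]):
        fs = F[:, j][orders[j]]
        val += w1 * np.sum(np.abs(np.diff(fs))) + w2 * np.sqrt(np.mean(F[:, j] ** 2))
    return float(val)


def solve_additive_tv0(X, y, lam, w1=None, w2=None):
    """Generic convex solve of the whole additive model (gaussian, TV-0).

    Variables: intercept + the n*p component values.  Smoothed L-BFGS with
    continuation; feasible for n <= 25, p <= 3.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w1 = lam * lam if w1 is None else w1
    w2 = lam if w2 is None else w2
    orders = [np.argsort(X[:, j], kind="stable") for j in range(p)]

    def fg(v, eps):
        beta = v[0]
        F = v[1:].reshape(n, p)
        resid = beta + F.sum(axis=1) - y
        val = 0.5 * np.mean(resid**2)
        G = np.tile((resid / n)[:, None], (1, p))
        gbeta = resid.mean()
        for j in range(p):
            o = orders[j]
            fs = F[o, j]
            d = np.diff(fs)
            val += w1 * np.sum(_smooth_abs(d, eps))
            gd = w1 * _smooth_abs_grad(d, eps)
            gs = np.zeros(n)
            gs[1:] += gd
            gs[:-1] -= gd
            G[o, j] += gs
            nf = np.sqrt(np.mean(F[:, j] ** 2) + eps * eps)
            val += w2 * nf
            G[:, j] += w2 * F[:, j] / (n * nf)
        return val, np.concatenate([[gbeta], G.ravel()])

    v = smoothed_minimize(fg, np.zeros(1 + n * p))
    return v[0], v[1:].reshape(n, p)
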