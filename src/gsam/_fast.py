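"""Compiled numerical kernels for the univariate penalized smoothers.

Everything here works on the *sorted, tie-collapsed* grid and in "sum
scale" (objectives multiplied by the total sample count n), which keeps
the kernels free of the empirical-norm bookkeeping done by the callers in
:mod:`gsam.penalties`.

Kernels
-------
``tv1d_condat``
    Exact O(n) direct solver for unweighted total-variation denoising
    (fused signal approximator), the k=0 structural smoother and the inner
    step of the trend-filtering splitting scheme.
``tf_admm``
    Specialized ADMM for k-th order trend filtering on an arbitrary grid:
    the variable z = (scaled k-th divided difference of f) turns the
    penalty into an ordinary TV norm on z, so the z-update is an exact TV
    denoise and the f-update a banded linear solve.  Stops on a duality
    gap computed from a projected dual candidate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# total variation denoising, Condat's direct algorithm
# ---------------------------------------------------------------------------


@njit(cache=False)
def tv1d_condat(y, lam):
    """argmin_x 0.5*sum((y-x)^2) + lam*sum(|x_{i+1}-x_i|), exact in O(n)."""
    n = y.size
    x = np.empty(n)
    if n == 0:
        return x
    if n == 1 or lam <= 0.0:
        x[:] = y
        return x
    N = n - 1
    k = 0
    k0 = 0
    km = 0
    kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        # remaining segment is the single last point
        if k == N:
            x[N] = vmin + umin
            return x
        # scan forward until the tube forces a jump or the end is reached
        while k < N:
            if y[k + 1] + umin < vmin - lam:
                # negative jump at km
                for i in range(k0, km + 1):
                    x[i] = vmin
                k = km + 1
                k0 = k
                km = k
                kp = k
                vmin = y[k]
                vmax = y[k] + 2.0 * lam
                umin = lam
                umax = -lam
            elif y[k + 1] + umax > vmax + lam:
                # positive jump at kp
                for i in range(k0, kp + 1):
                    x[i] = vmax
                k = kp + 1
                k0 = k
                km = k
                kp = k
                vmin = y[k] - 2.0 * lam
                vmax = y[k]
                umin = lam
                umax = -lam
            else:
                # extend the current segment
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    km = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kp = k
        # boundary handling at k == N
        if umin < 0.0:
            # lower string breaks: negative jump at km, restart after it
            for i in range(k0, km + 1):
                x[i] = vmin
            k = km + 1
            k0 = k
            km = k
            vmin = y[k]
            umin = lam
            umax = y[k] + lam - vmax
        elif umax > 0.0:
            # upper string breaks: positive jump at kp
            for i in range(k0, kp + 1):
                x[i] = vmax
            k = kp + 1
            k0 = k
            kp = k
            vmax = y[k]
            umax = -lam
            umin = y[k] - lam - vmin
        else:
            v = vmin + umin / (k - k0 + 1)
            for i in range(k0, N + 1):
                x[i] = v
            return x


# ---------------------------------------------------------------------------
# banded Cholesky (lower storage), bandwidth <= 2 in practice
# ---------------------------------------------------------------------------


@njit(cache=False)
def _band_cholesky(ab):
    """In-place-free banded Cholesky; ab[j, i] = A[i+j, i], j = 0..b."""
    bw = ab.shape[0] - 1
    m = ab.shape[1]
    L = np.zeros_like(ab)
    for i in range(m):
        s = ab[0, i]
        lo = i - bw if i - bw > 0 else 0
        for kc in range(lo, i):
            s -= L[i - kc, kc] * L[i - kc, kc]
        L[0, i] = np.sqrt(s)
        for r in range(1, bw + 1):
            row = i + r
            if row >= m:
                break
            s = ab[r, i]
            lo = row - bw if row - bw > 0 else 0
            for kc in range(lo, i):
                s -= L[row - kc, kc] * L[i - kc, kc]
            L[r, i] = s / L[0, i]
    return L


@njit(cache=False)
def _band_solve(L, rhs):
    """Solve L L^T x = rhs with L from :func:`_band_cholesky`."""
    bw = L.shape[0] - 1
    m = L.shape[1]
    z = np.empty(m)
    for i in range(m):
        s = rhs[i]
        lo = 1
        hi = bw if bw < i else i
        for j in range(lo, hi + 1):
            s -= L[j, i - j] * z[i - j]
        z[i] = s / L[0, i]
    x = np.empty(m)
    for i in range(m - 1, -1, -1):
        s = z[i]
        hi = bw if i + bw < m else m - 1 - i
        for j in range(1, hi + 1):
            s -= L[j, i] * x[i + j]
        x[i] = s / L[0, i]
    return x


# ---------------------------------------------------------------------------
# trend filtering ADMM
# ---------------------------------------------------------------------------


@njit(cache=False)
def _dk_matvec(coef, f, k):
    """z = D_k f for the banded difference operator given by coef rows."""
    mz = coef.shape[0]
    z = np.empty(mz)
    for i in range(mz):
        s = 0.0
        for j in range(k + 1):
            s += coef[i, j] * f[i + j]
        z[i] = s
    return z


@njit(cache=False)
def _dk_rmatvec(coef, z, k, m):
    """f = D_k^T z."""
    out = np.zeros(m)
    for i in range(coef.shape[0]):
        for j in range(k + 1):
            out[i + j] += coef[i, j] * z[i]
    return out


@njit(cache=False)
def _factor_f_update(w, coef, k, rho):
    """Banded Cholesky of W + rho * D_k^T D_k (bandwidth k)."""
    m = w.size
    ab = np.zeros((k + 1, m))
    ab[0, :] = w
    for i in range(coef.shape[0]):
        for a in range(k + 1):
            for b in range(a, k + 1):
                ab[b - a, i + a] += rho * coef[i, a] * coef[i, b]
    return _band_cholesky(ab)


@njit(cache=False)
def _tridiag_solve_ddt(c):
    """Solve (D1 D1^T) mu = D1 c, with D1 the plain first difference.

    D1 D1^T is the tridiagonal matrix with 2 on the diagonal and -1 off it.
    """
    mz = c.size
    m = mz - 1
    mu = np.zeros(m)
    if m <= 0:
        return mu
    rhs = np.empty(m)
    for i in range(m):
        rhs[i] = c[i + 1] - c[i]
    # Thomas algorithm for the (2, -1) tridiagonal system
    cp = np.empty(m)
    dp = np.empty(m)
    cp[0] = -1.0 / 2.0
    dp[0] = rhs[0] / 2.0
    for i in range(1, m):
        denom = 2.0 + cp[i - 1]
        cp[i] = -1.0 / denom
        dp[i] = (rhs[i] + dp[i - 1]) / denom
    mu[m - 1] = dp[m - 1]
    for i in range(m - 2, -1, -1):
        mu[i] = dp[i] - cp[i] * mu[i + 1]
    return mu










@njit(cache=False)
def tf_admm(r, w, coef, k, lam, rho0, gap_tol, max_iter, z0, u0):
    """Trend filtering: min_f 0.5*sum w (r-f)^2 + lam * TV(D_k f).

    ``coef`` holds the rows of the scaled k-th divided-difference operator
    (k+1 entries each); the penalty is the l1 norm of the plain first
    difference of z = D_k f, i.e. the discrete k-th order total variation.
    The stopping rule is a duality gap: at convergence rho*u lies in the
    subdifferential of lam*||D1 z||_1, so the dual candidate solves
    D1^T mu = rho*u in least squares (a fixed tridiagonal system) and is
    clipped to the box |mu| <= lam.
    Returns (f, z, u, rho, gap, iters); (z, u, rho) allow warm restarts.
    """
    m = r.size
    mz = coef.shape[0]
    if mz <= 1:
        # penalty has no jump terms: exact interpolation
        return r.copy(), z0, u0, rho0, 0.0, 0
    rho = rho0
    z = z0.copy()
    u = u0.copy()
    L = _factor_f_update(w, coef, k, rho)
    wr = w * r
    f = r.copy()
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rhs = wr + rho * _dk_rmatvec(coef, z - u, k, m)
        f = _band_solve(L, rhs)
        dkf = _dk_matvec(coef, f, k)
        z_old = z
        # over-relaxation (alpha = 1.8) speeds the splitting iteration
        dk_rel = 1.8 * dkf + (-0.8) * z_old
        z = tv1d_condat(dk_rel + u, lam / rho)
        u = u + dk_rel - z
        if it % 10 == 0 or it == max_iter:
            mu = _tridiag_solve_ddt(rho * u)
            for i in range(mu.size):
                if mu[i] > lam:
                    mu[i] = lam
                elif mu[i] < -lam:
                    mu[i] = -lam
            # A^T mu with A = D1 D_k
            d1t_mu = np.zeros(mz)
            for i in range(mu.size):
                d1t_mu[i] -= mu[i]
                d1t_mu[i + 1] += mu[i]
            at_mu = _dk_rmatvec(coef, d1t_mu, k, m)
            # primal value at f
            pval = 0.0
            for i in range(m):
                pval += 0.5 * w[i] * (r[i] - f[i]) ** 2
            for i in range(mz - 1):
                pval += lam * abs(dkf[i + 1] - dkf[i])
            # dual value g(mu) = mu^T A r - 0.5 || W^{-1/2} A^T mu ||^2
            gval = 0.0
            for i in range(m):
                gval += at_mu[i] * r[i] - 0.5 * at_mu[i] * at_mu[i] / w[i]
            gap = pval - gval
            if gap <= gap_tol:
                break
            # residual balancing
            rp = 0.0
            for i in range(mz):
                rp += (dkf[i] - z[i]) ** 2
            rd = 0.0
            dz = _dk_rmatvec(coef, z - z_old, k, m)
            for i in range(m):
                rd += (rho * dz[i]) ** 2
            if rp > 100.0 * rd and rho < 1e10:
                rho *= 2.0
                u = u / 2.0
                L = _factor_f_update(w, coef, k, rho)
            elif rd > 100.0 * rp and rho > 1e-10:
                rho /= 2.0
                u = u * 2.0
                L = _factor_f_update(w, coef, k, rho)
    return f, z, u, rho, gap, it


@njit(cache=False)
def tv_weighted_admm(r, w, lam, gap_tol, max_iter):
    """Weighted k=0 TV denoising via the same splitting with z = f."""
    m = r.size
    coef = np.ones((m, 1))
    z0 = r.copy()
    u0 = np.zeros(m)
    rho = np.mean(w)
    f, _, _, _, gap, it = tf_admm(r, w, coef, 0, lam, rho, gap_tol, max_iter, z0, u0)
    return f, gap, it


def warm_up() -> None:
    """Trigger JIT compilation of all kernels on tiny inputs."""
    y = np.array([1.0, -1.0, 2.0, 0.5])
    tv1d_condat(y, 0.3)
    w = np.ones(4)
    coef = np.array([[-1.0, 1.0], [-1.0, 1.0], [-1.0, 1.0]])
    tf_admm(y, w, coef, 1, 0.1, 1.0, 1e-10, 50, np.zeros(3), np.zeros(3))
    tv_weighted_admm(y, w, 0.2, 1e-10, 50)
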