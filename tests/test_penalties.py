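"""Univariate prox operators: printed identities, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_prox_instance
from gsam.penalties import (
    FeatureDesign,
    PenaltySpec,
    ProxProblem,
    dual_norm,
    dual_norm_check,
    emp_norm,
    match_lambda,
    penalty_value,
    prox_monotone,
    prox_subspace,
    prox_tv,
    prox_univariate,
    smooth_spline,
    soft_scale,
)
from oracles import (
    diff_operator,
    isotonic_qp,
    sobolev_operator,
    solve_univariate,
    univariate_objective,
)


# ---------------------------------------------------------------------------
# soft-scaling
# ---------------------------------------------------------------------------


def test_soft_scale_printed_example():
    f = np.array([2.0, -2.0, 2.0, -2.0])  # ||f||_n = 2
    out = soft_scale(f, 0.5)
    np.testing.assert_allclose(out, 0.75 * f)
    assert emp_norm(out) == pytest.approx(1.5)


def test_soft_scale_identity_and_zero():
    f = np.array([1.0, 2.0, -3.0])
    np.testing.assert_array_equal(soft_scale(f, 0.0), f)
    assert np.all(soft_scale(f, emp_norm(f)) == 0.0)
    assert np.all(soft_scale(f, emp_norm(f) + 1.0) == 0.0)
    assert np.all(soft_scale(np.zeros(3), 0.2) == 0.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    vals=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
    lam=st.floats(0, 10),
)
def test_soft_scale_norm_law(vals, lam):
    """||f_hat||_n = (||f||_n - lambda2)_+ holds exactly."""
    f = np.array(vals)
    out = soft_scale(f, lam)
    assert emp_norm(out) == pytest.approx(max(0.0, emp_norm(f) - lam), abs=1e-12)
    # output is a nonnegative multiple of the input
    if emp_norm(out) > 0:
        ratio = out[np.argmax(np.abs(f))] / f[np.argmax(np.abs(f))]
        assert ratio >= 0
        np.testing.assert_allclose(out, ratio * f, atol=1e-9)


# ---------------------------------------------------------------------------
# structural smoothers: fixed points and small oracles
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("k", [0, 1, 2])
def test_tv_constant_is_fixed_point(k, rng):
    x = np.sort(rng.uniform(-2, 2, 12))
    r = np.full(12, 3.14)
    fit = prox_tv(ProxProblem(r, x, 0.7, 0.0), k=k)
    np.testing.assert_allclose(fit.values, r, atol=1e-8)
    assert fit.struct_value == pytest.approx(0.0, abs=1e-8)


def test_tv0_large_lambda_gives_mean(rng):
    x = np.sort(rng.uniform(-2, 2, 15))
    r = rng.standard_normal(15)
    fit = prox_tv(ProxProblem(r, x, 100.0, 0.0), k=0)
    np.testing.assert_allclose(fit.values, r.mean(), atol=1e-8)


def test_tv0_three_point_oracle():
    """r=(0,3,0) at x=(1,2,3), k=0, lam1=0.5 vs generic convex oracle."""
    r = np.array([0.0, 3.0, 0.0])
    x = np.array([1.0, 2.0, 3.0])
    fit = prox_tv(ProxProblem(r, x, 0.5, 0.0), k=0)
    f_orc = solve_univariate(r, x, "tv", 0.5, 0.0, k=0)
    D = diff_operator(x, 0)
    o1 = univariate_objective(fit.values, r, "tv", 0.5, 0.0, D=D)
    o2 = univariate_objective(f_orc, r, "tv", 0.5, 0.0, D=D)
    assert o1 == pytest.approx(o2, abs=1e-6)


def test_subspace_projection_contracts(rng):
    x = np.sort(rng.uniform(-2, 2, 20))
    B = np.column_stack([x, x**2])
    Bc = B - B.mean(axis=0)
    # r already in the span projects to itself
    r = Bc @ np.array([1.0, -0.5])
    fit = prox_subspace(ProxProblem(r, x, 0.0, 0.0), basis=B)
    np.testing.assert_allclose(fit.values, r, atol=1e-10)
    assert fit.struct_value == 0.0
    # r orthogonal to the span projects to zero
    q, _ = np.linalg.qr(Bc)
    r_perp = rng.standard_normal(20)
    r_perp -= q @ (q.T @ r_perp)
    fit = prox_subspace(ProxProblem(r_perp, x, 0.0, 0.0), basis=B)
    np.testing.assert_allclose(fit.values, 0.0, atol=1e-10)


def test_subspace_normal_equations_oracle(rng):
    x = np.sort(rng.uniform(-2, 2, 25))
    B = np.column_stack([x, x**2])
    Bc = B - B.mean(axis=0)
    r = rng.standard_normal(25)
    fit = prox_subspace(ProxProblem(r, x, 0.0, 0.0), basis=B)
    coef = np.linalg.solve(Bc.T @ Bc, Bc.T @ r)
    np.testing.assert_allclose(fit.values, Bc @ coef, atol=1e-8)


def test_subspace_rank_deficient_basis(rng):
    x = np.sort(rng.uniform(-2, 2, 15))
    B = np.column_stack([x, 2 * x, x**2])  # duplicated direction
    r = rng.standard_normal(15)
    fit = prox_subspace(ProxProblem(r, x, 0.0, 0.0), basis=B)
    assert np.all(np.isfinite(fit.values))


def test_monotone_simple_cases():
    x = np.array([0.0, 1.0])
    fit = prox_monotone(ProxProblem(np.array([2.0, 1.0]), x, 0.0, 0.0))
    np.testing.assert_allclose(fit.values, [1.5, 1.5])
    r = np.array([1.0, 2.0, 2.5])
    fit = prox_monotone(ProxProblem(r, np.array([0.0, 1.0, 2.0]), 0.0, 0.0))
    np.testing.assert_allclose(fit.values, r)


def test_monotone_qp_oracle():
    r = np.array([1.0, 3.0, 2.0, 4.0])
    x = np.arange(4.0)
    fit = prox_monotone(ProxProblem(r, x, 0.0, 0.0))
    np.testing.assert_allclose(fit.values, isotonic_qp(r), atol=1e-8)


def test_smooth_spline_null_space_and_limits(rng):
    # jittered regular grid: all gaps above the sub-resolution merge scale
    x = np.linspace(-2, 2, 20) + rng.uniform(-0.05, 0.05, 20)
    r_lin = 0.3 + 1.7 * x
    fit = smooth_spline(r_lin, x, 5.0)
    np.testing.assert_allclose(fit.values, r_lin, atol=1e-8)
    assert fit.struct_value == pytest.approx(0.0, abs=1e-7)
    r = rng.standard_normal(20)
    fit0 = smooth_spline(r, x, 0.0)
    np.testing.assert_allclose(fit0.values, r, atol=1e-10)
    fit_inf = smooth_spline(r, x, 1e10)
    V = np.column_stack([np.ones_like(x), x])
    line = V @ np.linalg.lstsq(V, r, rcond=None)[0]
    np.testing.assert_allclose(fit_inf.values, line, atol=1e-3)


# ---------------------------------------------------------------------------
# dual norm and the squared-penalty adapter
# ---------------------------------------------------------------------------


def test_dual_norm_identity_is_self_dual(rng):
    v = rng.standard_normal(6)
    assert dual_norm(v, np.eye(6), q=2) == pytest.approx(np.linalg.norm(v))


def test_dual_norm_difference_row():
    assert dual_norm(np.array([1.0, -1.0]), np.array([[1.0, -1.0]]), q=2) == pytest.approx(1.0)


def test_dual_norm_check_linear_target(rng):
    x = np.linspace(-2, 2, 15) + rng.uniform(-0.05, 0.05, 15)
    r = -0.5 + 2.0 * x
    out = dual_norm_check(ProxProblem(r, x, 0.0, 0.0), PenaltySpec("sobolev", k=2))
    assert out["threshold"] == pytest.approx(0.0, abs=1e-10)
    assert out["shrink_to_null"]
    np.testing.assert_allclose(out["null_fit"].values, r, atol=1e-8)


def test_dual_norm_check_threshold_is_sharp(rng):
    """Just above the threshold the sobolev fit is the affine null fit;
    just below it is not."""
    x = np.sort(rng.uniform(-2.5, 2.5, 20))
    r = np.sin(x) - np.mean(np.sin(x))
    out = dual_norm_check(ProxProblem(r, x, 0.0, 0.0), PenaltySpec("sobolev", k=2))
    thr = out["threshold"]
    assert thr > 0
    above = prox_univariate(ProxProblem(r, x, 1.01 * thr, 0.0), PenaltySpec("sobolev", k=2))
    np.testing.assert_allclose(above.values, out["null_fit"].values, atol=1e-6)
    below = prox_univariate(ProxProblem(r, x, 0.8 * thr, 0.0), PenaltySpec("sobolev", k=2))
    assert np.abs(below.values - out["null_fit"].values).max() > 1e-4


def test_dual_norm_check_rejects_unrepresentable_penalty(rng):
    prob = ProxProblem(rng.standard_normal(5), np.arange(5.0), 0.1, 0.0)
    with pytest.raises(NotImplementedError):
        dual_norm_check(prob, PenaltySpec("monotone"))


def test_match_lambda_stationarity_and_grid_search(rng):
    """tau*lt*Pst(f) = lambda1 within 1e-6, and the matched fit beats a
    200-point lambda-tilde grid search in the semi-norm objective."""
    pen = PenaltySpec("sobolev", k=2)
    for _ in range(8):
        n = int(rng.integers(10, 51))
        x = np.sort(rng.uniform(-2.5, 2.5, n))
        r = rng.standard_normal(n)
        r -= r.mean()
        prob = ProxProblem(r, x, 0.0, 0.0)
        check = dual_norm_check(prob, pen)
        lam1 = 0.3 * check["threshold"]
        design = prob.design
        out = match_lambda(r, x, lam1, pen, design=design)
        fit = out["fit"]
        assert 2 * out["lambda_tilde"] * fit.struct_value == pytest.approx(lam1, rel=1e-6)
        # objectives evaluated on the package's fitting grid
        D = sobolev_operator(design.x_unique)
        wg = design.weights
        rg = design.collapse(r)

        def obj(values):
            return univariate_objective(
                design.collapse(values), rg, "sobolev", lam1, 0.0, D=D, q=2, weights=wg
            )

        obj_matched = obj(fit.values)
        grid = np.geomspace(1e-8, emp_norm(r), 200)
        objs = [obj(smooth_spline(r, x, lt, design=design).values) for lt in grid]
        assert obj_matched <= min(objs) + 1e-5 * (1 + abs(min(objs)))


def test_match_lambda_warm_start_agrees(rng):
    x = np.sort(rng.uniform(-2.5, 2.5, 30))
    r = np.sin(2 * x)
    r -= r.mean()
    out1 = match_lambda(r, x, 0.05, PenaltySpec("sobolev", k=2))
    out2 = match_lambda(
        r, x, 0.05, PenaltySpec("sobolev", k=2), lambda_tilde_init=out1["lambda_tilde"]
    )
    assert out2["lambda_tilde"] == pytest.approx(out1["lambda_tilde"], rel=1e-6)


# ---------------------------------------------------------------------------
# full prox: dispatch, early exit, invariants
# ---------------------------------------------------------------------------

ALL_KINDS = [
    PenaltySpec("tv", k=0),
    PenaltySpec("tv", k=1),
    PenaltySpec("tv", k=2),
    PenaltySpec("sobolev", k=2),
    PenaltySpec("subspace", M=2),
    PenaltySpec("monotone"),
]


@pytest.mark.parametrize("pen", ALL_KINDS, ids=lambda p: f"{p.kind}{p.k}")
def test_prox_early_exit_zero(pen, rng):
    r, x, lam1, _ = random_prox_instance(rng)
    lam2 = emp_norm(r) * 1.0001
    fit = prox_univariate(ProxProblem(r, x, lam1, lam2), pen)
    assert np.all(fit.values == 0.0)
    assert fit.emp_norm == 0.0 and fit.struct_value == 0.0


@pytest.mark.parametrize("pen", ALL_KINDS[:4], ids=lambda p: f"{p.kind}{p.k}")
def test_prox_shift_equivariance(pen, rng):
    """Structural smoothing commutes with constant shifts (lambda2 = 0)."""
    r, x, lam1, _ = random_prox_instance(rng)
    f0 = prox_univariate(ProxProblem(r, x, lam1, 0.0), pen).values
    f1 = prox_univariate(ProxProblem(r + 2.5, x, lam1, 0.0), pen).values
    np.testing.assert_allclose(f1, f0 + 2.5, atol=2e-5)


def test_prox_monotone_shrinkage_in_lambda2(rng):
    r, x, lam1, _ = random_prox_instance(rng)
    pen = PenaltySpec("tv", k=0)
    norms = [
        prox_univariate(ProxProblem(r, x, lam1, l2), pen).emp_norm
        for l2 in np.linspace(0, emp_norm(r) * 1.1, 12)
    ]
    assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


def test_prox_struct_shrinkage_in_lambda1(rng):
    r, x, _, _ = random_prox_instance(rng)
    pen = PenaltySpec("tv", k=0)
    vals = [
        prox_univariate(ProxProblem(r, x, l1, 0.0), pen).struct_value
        for l1 in np.geomspace(1e-3, 2.0, 12)
    ]
    assert all(a >= b - 1e-8 for a, b in zip(vals, vals[1:]))


def test_prox_ties_collapse_to_weighted_fit(rng):
    """Duplicate x values share one fitted value equal to the weighted fit
    on the collapsed grid."""
    x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 3.0, 3.0])
    r = rng.standard_normal(7)
    for pen in (PenaltySpec("tv", k=0), PenaltySpec("sobolev", k=2), PenaltySpec("monotone")):
        fit = prox_univariate(ProxProblem(r, x, 0.05, 0.0), pen)
        assert fit.values[1] == pytest.approx(fit.values[2], abs=1e-10)
        assert fit.values[4] == pytest.approx(fit.values[5], abs=1e-10)
        assert fit.values[5] == pytest.approx(fit.values[6], abs=1e-10)


def test_prox_single_point_returns_input():
    fit = prox_univariate(ProxProblem(np.array([1.5]), np.array([0.0]), 0.3, 0.0), PenaltySpec("tv", k=0))
    np.testing.assert_allclose(fit.values, [1.5])


def test_penalty_value_indicator_conventions(rng):
    x = rng.uniform(-2, 2, 10)  # unsorted on purpose
    d = FeatureDesign(x, PenaltySpec("monotone"))
    assert penalty_value(x, d) == 0.0  # f(x) = x is non-decreasing in x
    assert np.isinf(penalty_value(-x, d))
    d_sub = FeatureDesign(x, PenaltySpec("subspace", M=1))
    assert penalty_value(x - x.mean(), d_sub) == 0.0
    assert np.isinf(penalty_value(x**2, d_sub))


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        ProxProblem(np.ones(3), np.arange(3.0), -0.1, 0.0)
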