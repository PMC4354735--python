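import numpy as np
import pytest

from sgleeg import (GroupStructure, PenaltySpec, SolverSettings,
                    descent_direction_at_zero, fit, group_zero_test,
                    inner_coordinate_update, kkt_lambda_max, kkt_residual,
                    objective, solve_quadratic_subproblem)
from sgleeg.solver import _solve_group

from _oracles import golden_section, omega, sgl_prox
from conftest import make_instance

TIGHT = SolverSettings(outer_tol=1e-10, max_outer=1000, kkt_tol=1e-6,
                       inner_tol=1e-12, middle_tol=1e-12)


class TestInnerCoordinateUpdate:
    def test_zero_curvature_returns_zero(self):
        assert inner_coordinate_update(c=5.0, h=0.0, r=1.0, gamma=1.0,
                                       xi=1.0) == 0.0

    def test_closed_form_branch_r_zero(self):
        # c=5, h=1, xi=1, gamma=1: threshold 2, so beta = (2-5)/1 = -3
        assert inner_coordinate_update(5.0, 1.0, 0.0, 1.0, 1.0) == -3.0
        assert inner_coordinate_update(-5.0, 1.0, 0.0, 1.0, 1.0) == 3.0
        assert inner_coordinate_update(1.5, 1.0, 0.0, 1.0, 1.0) == 0.0

    def test_zero_branch_inside_xi(self):
        assert inner_coordinate_update(0.4, 2.0, 1.0, 0.5, 0.5) == 0.0
        assert inner_coordinate_update(-0.5, 2.0, 1.0, 0.5, 0.5) == 0.0

    def test_root_branch_matches_golden_section(self):
        c, h, r, gamma, xi = 2.0, 1.0, 1.0, 0.5, 0.5
        b = inner_coordinate_update(c, h, r, gamma, xi, tol=1e-12)
        bound = (abs(c) + gamma + xi) / h + 1.0
        ref = golden_section(lambda t: omega(t, c, h, r, gamma, xi),
                             -bound, bound)
        assert b == pytest.approx(ref, abs=1e-8)
        # stationarity: c + xi*s + h*b + gamma*b/sqrt(b^2+r) = 0
        resid = c - xi + h * b + gamma * b / np.sqrt(b * b + r)
        assert abs(resid) < 1e-10

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            inner_coordinate_update(1.0, -1.0, 0.0, 0.0, 0.0)


class TestGroupZeroTest:
    def test_zero_gradient_passes(self):
        spec = PenaltySpec(lam=0.5, alpha=0.5)
        assert group_zero_test(np.zeros(5), spec)

    def test_alpha_zero_reduces_to_group_norm_test(self, rng):
        g = rng.standard_normal(6)
        lam = np.linalg.norm(g)
        assert group_zero_test(g, PenaltySpec(lam=lam * 1.001, alpha=0.0))
        assert not group_zero_test(g, PenaltySpec(lam=lam * 0.999, alpha=0.0))

    def test_agrees_with_proximal_oracle_on_quadratic_subproblems(self):
        # for an isotropic quadratic with gradient g at 0, the prox of the
        # SGL penalty at -g decides exactly whether the solution is zero
        rng = np.random.default_rng(99)
        n_checked = 0
        for _ in range(100):
            d = rng.integers(2, 8)
            g = rng.standard_normal(d) * rng.uniform(0.5, 3)
            lam = rng.uniform(0.1, 3.0)
            alpha = rng.uniform(0.0, 1.0)
            spec = PenaltySpec(lam=lam, alpha=alpha)
            sol = sgl_prox(-g.copy(), 1.0, lam * (1 - alpha), lam * alpha,
                           [slice(0, d)], [1.0])
            oracle_zero = np.linalg.norm(sol) < 1e-12
            assert group_zero_test(g, spec) == oracle_zero
            n_checked += 1
        assert n_checked == 100


class TestDescentDirectionAtZero:
    def test_all_small_gradients_give_zero(self):
        spec = PenaltySpec(lam=1.0, alpha=0.5)
        g = np.array([0.1, -0.3, 0.4])
        assert np.allclose(descent_direction_at_zero(g, spec), 0.0)

    def test_alpha_zero_is_steepest_descent(self, rng):
        g = rng.standard_normal(5)
        spec = PenaltySpec(lam=1.0, alpha=0.0)
        assert np.allclose(descent_direction_at_zero(g, spec), -g)

    def test_directional_derivative_negative(self, rng):
        # finite difference of the penalized quadratic at zero along Delta
        for _ in range(20):
            d = 4
            g = rng.standard_normal(d) * 2
            lam, alpha = 0.8, 0.4
            spec = PenaltySpec(lam=lam, alpha=alpha)
            if group_zero_test(g, spec):
                continue
            delta = descent_direction_at_zero(g, spec)
            assert np.any(delta != 0)
            h = np.abs(rng.standard_normal(d)) + 0.5
            t = 1e-7

            def f(v):
                return g @ v + 0.5 * (h * v * v).sum() \
                    + lam * (1 - alpha) * np.linalg.norm(v) \
                    + lam * alpha * np.abs(v).sum()
            assert (f(t * delta) - f(np.zeros(d))) / t < 0


class TestQuadraticSubproblem:
    def test_zero_gradient_gives_zero(self):
        groups = GroupStructure.from_sizes(2, 3)
        blocks = [2.0 * np.eye(3).reshape(3, 1, 3, 1)] * 2
        beta, _ = solve_quadratic_subproblem(
            np.zeros((6, 1)), blocks, np.zeros((6, 1)), groups,
            PenaltySpec(lam=0.5, alpha=0.5), SolverSettings())
        assert np.all(beta == 0.0)

    def test_group_soft_threshold_closed_form_isotropic(self, rng):
        # single group, alpha=0, H = h*I: beta = max(0, 1 - gamma/||g||)(-g/h)
        d, h, lam = 5, 2.0, 0.4
        g = rng.standard_normal(d)
        groups = GroupStructure.from_sizes(1, d)
        blocks = [h * np.eye(d).reshape(d, 1, d, 1)]
        spec = PenaltySpec(lam=lam, alpha=0.0)
        settings = SolverSettings(inner_tol=1e-12, middle_tol=1e-12)
        beta, _ = solve_quadratic_subproblem(
            g[:, None], blocks, np.zeros((d, 1)), groups, spec, settings)
        shrink = max(0.0, 1.0 - lam / np.linalg.norm(g))
        expected = shrink * (-g / h)
        assert np.allclose(beta[:, 0], expected, atol=1e-9)

    def test_two_coefficient_agreement_with_coordinatewise_golden_section(self):
        rng = np.random.default_rng(5)
        g = rng.standard_normal(2)
        h = np.array([1.5, 0.7])
        lam, alpha = 0.3, 0.5
        gamma, xi = lam * (1 - alpha), lam * alpha
        settings = SolverSettings(inner_tol=1e-13, middle_tol=1e-13)
        v = _solve_group(g[:, None], np.diag(h).reshape(2, 1, 2, 1), gamma,
                         xi, np.zeros((2, 1)), settings)

        # oracle: exhaustive coordinatewise golden-section minimization
        w = np.zeros(2)
        for _ in range(200):
            for j in range(2):
                other = w[1 - j]

                def fj(t, j=j, other=other):
                    vv = np.array([0.0, 0.0])
                    vv[j], vv[1 - j] = t, other
                    return g @ vv + 0.5 * (h * vv * vv).sum() \
                        + gamma * np.sqrt((vv * vv).sum()) \
                        + xi * np.abs(vv).sum()
                w[j] = golden_section(fj, -5.0, 5.0)
        assert np.allclose(v[:, 0], w, atol=1e-6)


class TestFit:
    def test_all_zero_at_lambda_max(self):
        for seed in (0, 1, 2):
            Z, Y, groups, _ = make_instance(seed=seed)
            for alpha in (0.0, 0.5, 1.0):
                lam_max = kkt_lambda_max(Z, Y, groups, alpha)
                res = fit(Z, Y, groups, PenaltySpec(lam=lam_max, alpha=alpha))
                assert np.all(res.beta == 0.0), (seed, alpha)

    def test_nonzero_below_lambda_max(self):
        for seed in (0, 1, 2):
            Z, Y, groups, _ = make_instance(seed=seed)
            lam_max = kkt_lambda_max(Z, Y, groups, 0.5)
            res = fit(Z, Y, groups,
                      PenaltySpec(lam=0.9 * lam_max, alpha=0.5))
            assert np.any(res.beta != 0.0), seed

    def test_objective_nonincreasing(self, small_instance):
        Z, Y, groups, _ = small_instance
        lam = 0.2 * kkt_lambda_max(Z, Y, groups, 0.5)
        res = fit(Z, Y, groups, PenaltySpec(lam=lam, alpha=0.5))
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_bitwise_deterministic(self, small_instance):
        Z, Y, groups, _ = small_instance
        spec = PenaltySpec(lam=0.1 * kkt_lambda_max(Z, Y, groups, 0.5),
                           alpha=0.5)
        r1 = fit(Z, Y, groups, spec)
        r2 = fit(Z, Y, groups, spec)
        assert np.array_equal(r1.beta, r2.beta)
        assert np.array_equal(r1.intercept, r2.intercept)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    def test_reported_zeros_are_exact(self, small_instance):
        Z, Y, groups, _ = small_instance
        lam = 0.4 * kkt_lambda_max(Z, Y, groups, 0.5)
        res = fit(Z, Y, groups, PenaltySpec(lam=lam, alpha=0.5), TIGHT)
        small = np.abs(res.beta) < 1e-8
        # every "numerically small" coefficient is a hard zero
        assert np.all(res.beta[small] == 0.0)
        assert small.any() and (~small).any()

    def test_flagged_when_not_converged(self, small_instance):
        Z, Y, groups, _ = small_instance
        lam = 0.05 * kkt_lambda_max(Z, Y, groups, 0.5)
        settings = SolverSettings(max_outer=1, outer_tol=1e-14)
        res = fit(Z, Y, groups, PenaltySpec(lam=lam, alpha=0.5), settings)
        assert not res.converged
        assert "maximum outer iterations" in res.message


class TestKKT:
    def test_zero_at_lambda_max_with_zero_beta(self, small_instance):
        Z, Y, groups, _ = small_instance
        lam_max = kkt_lambda_max(Z, Y, groups, 0.5)
        res = fit(Z, Y, groups, PenaltySpec(lam=lam_max, alpha=0.5), TIGHT)
        assert res.kkt < 1e-6

    def test_positive_at_random_nonoptimal_point(self, small_instance, rng):
        Z, Y, groups, _ = small_instance
        spec = PenaltySpec(lam=1.0, alpha=0.5)
        beta = rng.standard_normal((Z.shape[1], 1))
        assert kkt_residual(Z, Y, beta, groups, spec) > 0.1

    def test_objective_local_optimality(self, small_instance, rng):
        # random perturbations around the converged point never decrease
        # the penalized objective
        Z, Y, groups, _ = small_instance
        spec = PenaltySpec(lam=0.3 * kkt_lambda_max(Z, Y, groups, 0.5),
                           alpha=0.5)
        res = fit(Z, Y, groups, spec, TIGHT)
        f0 = objective(Z, Y, res.beta, groups, spec, intercept=res.intercept)
        for _ in range(30):
            pert = res.beta + 1e-4 * rng.standard_normal(res.beta.shape)
            f1 = objective(Z, Y, pert, groups, spec, intercept=res.intercept)
            assert f1 >= f0 - 1e-10
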