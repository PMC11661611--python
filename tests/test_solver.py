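"""Tridiagonal assembly/solve, RHS construction, and the implicit march."""

import dataclasses

import numpy as np
import pytest

from fuzzyfdm import (
    SchemeParams,
    assemble_tridiagonal,
    build_rhs,
    compute_weights,
    solve_branch,
    solve_fuzzy,
    thomas_solve,
)

from conftest import backward_euler_branch, literal_rhs, scheme_residual


class TestAssembly:
    def test_benchmark_coefficients(self):
        sub, diag, sup = assemble_tridiagonal(0.04, 3)
        assert np.allclose(diag, 1.08)
        assert np.allclose(sub, -0.04) and np.allclose(sup, -0.04)
        assert len(sub) == len(sup) == 2

    def test_vanishing_coupling_gives_identity(self):
        sub, diag, sup = assemble_tridiagonal(1e-300, 4)
        assert np.allclose(diag, 1.0)
        assert np.allclose(sub, 0.0, atol=1e-299)

    @pytest.mark.parametrize("tau", [0.01, 1.0, 100.0, 1e6])
    def test_dominance_margin_is_one(self, tau):
        sub, diag, sup = assemble_tridiagonal(tau, 5)
        margin = diag[1:-1] - np.abs(sub[:-1]) - np.abs(sup[1:])
        assert np.allclose(margin, 1.0)


class TestThomasSolve:
    def test_identity_system(self):
        rhs = np.array([3.0, -1.0, 2.0])
        x = thomas_solve(np.zeros(2), np.ones(3), np.zeros(2), rhs)
        assert np.array_equal(x, rhs)

    def test_hand_eliminated_two_by_two(self):
        x = thomas_solve(
            np.array([-1.0]), np.array([2.0, 2.0]), np.array([-1.0]),
            np.array([1.0, 1.0]),
        )
        assert np.allclose(x, [1.0, 1.0])

    def test_matches_dense_and_banded_oracles(self):
        """200 random strictly diagonally dominant systems, sizes 2..50,
        against numpy dense solve and scipy banded solve."""
        from scipy.linalg import solve_banded

        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            sub = rng.uniform(-1, 1, n - 1)
            sup = rng.uniform(-1, 1, n - 1)
            diag = rng.uniform(1, 2, n) * np.sign(rng.uniform(-1, 1, n))
            diag += np.sign(diag) * (
                np.abs(np.r_[0.0, sub]) + np.abs(np.r_[sup, 0.0])
            )
            rhs = rng.uniform(-5, 5, n)
            A = np.diag(diag) + np.diag(sub, -1) + np.diag(sup, 1)
            expected = np.linalg.solve(A, rhs)
            got = thomas_solve(sub, diag, sup, rhs)
            assert np.allclose(got, expected, rtol=1e-12, atol=1e-14)
            ab = np.zeros((3, n))
            ab[0, 1:] = sup
            ab[1] = diag
            ab[2, :-1] = sub
            assert np.allclose(
                got, solve_banded((1, 1), ab, rhs), rtol=1e-12, atol=1e-14
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            thomas_solve(np.zeros(3), np.ones(3), np.zeros(2), np.ones(3))


class TestBuildRhs:
    def test_first_step_has_empty_memory(self):
        """At n=0 with no killing the RHS is u^0 plus boundary terms."""
        u0 = np.array([9.0, 1.0, 2.0, 3.0, 9.0])
        w = compute_weights(0.5, 5)
        rhs = build_rhs(u0[None, :], w, 0.0, tau=0.1, bc_next=(10.0, 20.0))
        assert np.allclose(rhs, [1.0 + 1.0, 2.0, 3.0 + 2.0])

    def test_classical_order_reduces_to_backward_euler_rhs(self):
        """With alpha=1 every weight vanishes: RHS = (1 - dt k) u^n plus
        boundary terms, regardless of the history depth."""
        rng = np.random.default_rng(3)
        history = rng.uniform(0, 1, (4, 6))
        w = compute_weights(1.0, 10)
        kappa = np.array([0.1, 0.2, 0.3, 0.4])
        rhs = build_rhs(history, w, kappa, tau=0.5, bc_next=(1.0, 2.0))
        expected = (1.0 - kappa) * history[-1, 1:-1]
        expected[0] += 0.5
        expected[-1] += 1.0
        assert np.allclose(rhs, expected)

    def test_matches_literal_summation_oracle(self):
        """Scripted 3-row history on 3 interior nodes, alpha=0.5, against
        the term-by-term evaluation of the printed update formula."""
        history = np.array(
            [
                [0.0, 1.0, 2.0, 3.0, 0.0],
                [0.1, 1.5, 1.8, 2.5, 0.1],
                [0.2, 1.2, 2.2, 2.1, 0.2],
            ]
        )
        w = compute_weights(0.5, 2)
        kappa = np.array([0.01, 0.02, 0.03])
        got = build_rhs(history, w, kappa, tau=0.354, bc_next=(0.3, 0.4))
        expected = literal_rhs(history, w.b, kappa, 0.354, (0.3, 0.4))
        assert np.allclose(got, expected, atol=1e-14)

    def test_short_weight_sequence_rejected(self):
        history = np.zeros((4, 5))
        with pytest.raises(ValueError, match="weights"):
            build_rhs(history, compute_weights(0.5, 2), 0.0, 0.1, (0.0, 0.0))


class TestSolveBranch:
    def test_constant_state_is_stationary(self, constant_problem):
        """Constants solve pure diffusion exactly at every alpha."""
        prob = constant_problem(value=2.0)
        for alpha in (0.3, 1.0):
            scheme = SchemeParams.from_mesh(alpha, 0.02, 0.5, 4.0, 0.1)
            u = solve_branch(prob, scheme)
            assert np.allclose(u, 2.0, atol=1e-13)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8, 1.0])
    def test_each_level_satisfies_the_update_relation(
        self, benchmark_problem, alpha
    ):
        """Substituting every computed row back into the literal implicit
        relation leaves residual <= 1e-10 (solver correctness independent
        of the physics)."""
        from fuzzyfdm.problems import defuzzify_problem

        spec, scheme = benchmark_problem(alpha)
        lower, _ = defuzzify_problem(spec, 0.3)
        u = solve_branch(lower, scheme)
        assert scheme_residual(u, lower, scheme) <= 1e-10

    def test_solution_is_linear_in_the_data(self, benchmark_problem,
                                            scaled_spec):
        """Scaling IC and BCs by c scales the whole history by c."""
        from fuzzyfdm.problems import defuzzify_problem

        spec, scheme = benchmark_problem(0.6)
        base, _ = defuzzify_problem(spec, 0.0)
        scaled, _ = defuzzify_problem(scaled_spec(spec, 2.0), 0.0)
        u1 = solve_branch(base, scheme)
        u2 = solve_branch(scaled, scheme)
        assert np.allclose(u2, 2.0 * u1, rtol=1e-13)

    def test_classical_limit_matches_backward_euler_oracle(
        self, benchmark_problem
    ):
        """At alpha=1 the memory term vanishes and the march coincides with
        an independently coded backward-Euler/central-difference solver."""
        from fuzzyfdm.problems import defuzzify_problem

        spec, scheme = benchmark_problem(1.0)
        for branch in defuzzify_problem(spec, 0.3):
            ours = solve_branch(branch, scheme)
            oracle = backward_euler_branch(branch, scheme)
            assert np.max(np.abs(ours - oracle)) <= 1e-12

    def test_boundary_and_initial_rows_are_sampled_data(
        self, benchmark_problem
    ):
        from fuzzyfdm.problems import defuzzify_problem

        spec, scheme = benchmark_problem(0.4)
        lower, _ = defuzzify_problem(spec, 0.0)
        u = solve_branch(lower, scheme)
        assert np.allclose(u[0], [lower.ic(x) for x in scheme.x])
        assert np.allclose(u[:, 0], [lower.bc_left(t) for t in scheme.t])
        assert np.allclose(u[:, -1], [lower.bc_right(t) for t in scheme.t])

    def test_large_mesh_ratio_stays_bounded(self, benchmark_problem):
        """tau >> 1 smoke test: the implicit solution stays within a modest
        factor of the data bound, with no oscillatory blow-up."""
        import dataclasses

        spec, _ = benchmark_problem(0.5)
        spec = dataclasses.replace(spec, t_final=1.0)
        scheme = SchemeParams.from_mesh(0.5, 0.5, 0.1, 5.0, 1.0)
        assert scheme.tau > 50
        from fuzzyfdm.problems import defuzzify_problem

        lower, _ = defuzzify_problem(spec, 0.0)
        u = solve_branch(lower, scheme)
        data_bound = max(
            np.max(np.abs(u[0])),
            np.max(np.abs(u[:, 0])),
            np.max(np.abs(u[:, -1])),
        )
        assert np.max(np.abs(u)) <= 2.0 * data_bound
        assert np.all(np.isfinite(u))

    def test_mismatched_domain_rejected(self, benchmark_problem):
        from fuzzyfdm.problems import defuzzify_problem

        spec, _ = benchmark_problem(0.5)
        lower, _ = defuzzify_problem(spec, 0.0)
        wrong = SchemeParams.from_mesh(0.5, 0.01, 0.5, 4.0, 0.05)
        with pytest.raises(ValueError, match="domain"):
            solve_branch(lower, wrong)


class TestSolveFuzzy:
    def test_core_level_collapses_the_envelope(self, benchmark_problem):
        spec, scheme = benchmark_problem(0.8)
        grid = solve_fuzzy(spec, 1.0, scheme)
        assert np.array_equal(grid.lower, grid.upper)
        assert grid.envelope_ok

    def test_initial_row_scales_with_the_support_endpoints(
        self, benchmark_problem
    ):
        """At t=0 the upper/lower ratio is exactly 1.25/0.75 (linear IC)."""
        spec, scheme = benchmark_problem(0.5)
        grid = solve_fuzzy(spec, 0.0, scheme)
        ratio = grid.upper[0] / grid.lower[0]
        assert np.allclose(ratio, 1.25 / 0.75, rtol=1e-13)

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.7])
    def test_envelope_holds_everywhere(self, benchmark_problem, r):
        spec, scheme = benchmark_problem(0.4)
        grid = solve_fuzzy(spec, r, scheme)
        assert grid.envelope_ok
        assert np.all(grid.lower <= grid.upper + 1e-15)

    def test_branches_are_monotone_in_r(self, benchmark_problem):
        """Lower-branch values rise and upper-branch values fall as r grows
        (nested cuts propagate through the linear solve)."""
        spec, scheme = benchmark_problem(0.6)
        grids = [solve_fuzzy(spec, r, scheme) for r in (0.0, 0.3, 0.7, 1.0)]
        for a, b in zip(grids, grids[1:]):
            assert np.all(a.lower <= b.lower + 1e-14)
            assert np.all(a.upper >= b.upper - 1e-14)
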