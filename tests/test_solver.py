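"""Interior-point solver: oracle equivalence, KKT optimality, structure."""

import math
import warnings

import numpy as np
import pytest

import sparseilt as si
from sparseilt.solver import (ConvergenceWarning, InteriorPointProblem,
                              InversionModel, SolverOptions, kkt_residual,
                              interior_point_solve, solve_inversion,
                              split_dictionary_problem)


def _toy_model(m=5, n=4, seed=0, lam1=0.1, lam2=0.05):
    rng = np.random.default_rng(seed)
    tg = si.build_time_grid(1.0, m)
    t2g = si.build_t2_grid(0.5, 20.0, n)
    K = si.build_kernel(tg, t2g)
    s = K.matrix @ np.abs(rng.normal(size=n)) + 0.05 * rng.normal(size=m)
    return InversionModel(kernel=K, s=s, lambda1=lam1, lambda2=lam2)


def _objective(model, f):
    r = model.kernel.matrix @ f - model.s
    return (0.5 * r @ r + model.lambda1 * np.abs(f).sum()
            + 0.5 * model.lambda2 * f @ f)


class TestSolveInversion:
    def test_zero_data_gives_zero_spectrum(self, small_kernel):
        model = InversionModel(kernel=small_kernel,
                               s=np.zeros(small_kernel.shape[0]),
                               lambda1=0.1, lambda2=0.1)
        spec = solve_inversion(model, SolverOptions(tol=1e-10))
        assert np.max(np.abs(spec.values)) < 1e-8
        assert kkt_residual(spec, model) < 1e-6

    def test_noise_free_delta_recovery(self, small_kernel, qp_oracle):
        """A single grid delta is recovered almost exactly at tiny lambda."""
        K = small_kernel.matrix
        j = 6
        s = K[:, j].copy()
        model = InversionModel(kernel=small_kernel, s=s,
                               lambda1=1e-8, lambda2=1e-8)
        spec = solve_inversion(model, SolverOptions(tol=1e-10))
        mass = spec.values.sum()
        assert spec.values[max(j - 1, 0):j + 2].sum() >= 0.99 * mass
        # agrees with the exhaustive active-set oracle (absolute slack at the
        # scale of the tiny penalties themselves)
        f_star, obj_star = qp_oracle(K, s, 1e-8, 1e-8)
        assert _objective(model, spec.values) <= obj_star + 1e-8

    def test_toy_objective_matches_oracle(self, qp_oracle):
        model = _toy_model(lam1=0.1, lam2=0.05)
        spec = solve_inversion(model)
        _, obj_star = qp_oracle(model.kernel.matrix, model.s, 0.1, 0.05)
        assert _objective(model, spec.values) == pytest.approx(obj_star, rel=1e-6)

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, seed, qp_oracle):
        """Objective within relative 1e-6 of independent enumeration, 50 draws."""
        rng = np.random.default_rng(1000 + seed)
        m = int(rng.integers(6, 31))
        n = int(rng.integers(3, 11))
        tg = si.build_time_grid(float(rng.uniform(0.2, 2.0)), m)
        t2g = si.build_t2_grid(0.3, float(rng.uniform(20, 200)), n)
        K = si.build_kernel(tg, t2g)
        s = (K.matrix @ np.abs(rng.normal(size=n))
             + 0.1 * rng.normal(size=m))
        lam1 = float(rng.uniform(0.001, 0.5))
        lam2 = float(rng.uniform(0.001, 0.5))
        model = InversionModel(kernel=K, s=s, lambda1=lam1, lambda2=lam2)
        spec = solve_inversion(model)
        _, obj_star = qp_oracle(K.matrix, s, lam1, lam2)
        assert _objective(model, spec.values) == pytest.approx(obj_star, rel=1e-6)
        assert spec.values.min() >= -1e-9 * max(spec.values.max(), 1e-30)
        assert kkt_residual(spec, model) < 1e-6

    def test_l1_and_l2_norm_monotonicity(self):
        """||f||_1 shrinks with lambda1; ||f||_2 shrinks with lambda2."""
        base = _toy_model(m=12, n=8, seed=3, lam1=0.0, lam2=0.0)
        l1_norms = []
        for lam1 in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            m = InversionModel(kernel=base.kernel, s=base.s,
                               lambda1=lam1, lambda2=0.01)
            l1_norms.append(np.abs(solve_inversion(m).values).sum())
        assert np.all(np.diff(l1_norms) <= 1e-8)
        l2_norms = []
        for lam2 in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            m = InversionModel(kernel=base.kernel, s=base.s,
                               lambda1=0.01, lambda2=lam2)
            l2_norms.append(np.linalg.norm(solve_inversion(m).values))
        assert np.all(np.diff(l2_norms) <= 1e-8)

    def test_l2_only_matches_tikhonov_filter_factors(self):
        """With bounds released and lambda1 = 0, the solution is the SVD
        solution with coefficients damped by sigma/(sigma^2 + lambda2)."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(20, 10))
        s = rng.normal(size=20)
        lam2 = 0.3
        problem = InteriorPointProblem(
            A=A, b=s, l=np.full(10, -np.inf), u=np.full(10, np.inf),
            d1=np.full(10, math.sqrt(lam2)), d2=np.ones(20))
        sol = interior_point_solve(problem, SolverOptions(tol=1e-12))
        U, sv, Vt = np.linalg.svd(A, full_matrices=False)
        x_star = Vt.T @ (sv / (sv ** 2 + lam2) * (U.T @ s))
        assert np.linalg.norm(sol.x - x_star) <= 1e-8 * np.linalg.norm(x_star)

    def test_gap_decreases_over_final_iterations(self):
        model = _toy_model(m=20, n=8, seed=5)
        spec = solve_inversion(model)
        tail = spec.gap_history[-5:]
        assert all(b <= a * (1 + 1e-6) for a, b in zip(tail, tail[1:]))

    def test_iteration_cap_warns_and_returns_partial(self):
        model = _toy_model(m=20, n=8, seed=5)
        with pytest.warns(ConvergenceWarning):
            spec = solve_inversion(model, SolverOptions(max_iter=2))
        assert not spec.converged
        assert spec.iterations == 2
        assert np.all(np.isfinite(spec.values))

    def test_non_conformable_model_raises(self, small_kernel):
        with pytest.raises(ValueError):
            InversionModel(kernel=small_kernel, s=np.zeros(3),
                           lambda1=0.1, lambda2=0.1)
        with pytest.raises(ValueError):
            InversionModel(kernel=small_kernel,
                           s=np.zeros(small_kernel.shape[0]),
                           lambda1=-0.1, lambda2=0.1)


class TestSplitDictionaryProblem:
    def test_identity_case_has_no_variable_doubling(self, small_kernel):
        model = InversionModel(kernel=small_kernel,
                               s=np.ones(small_kernel.shape[0]),
                               lambda1=0.2, lambda2=0.1)
        problem = split_dictionary_problem(model)
        m, n = small_kernel.shape
        assert problem.shape == (m, n)
        _, g, _ = problem.phi_eval(np.zeros(n))
        np.testing.assert_allclose(g, 0.2)  # L1 term reduces to lam1 * 1^T c

    def test_constraint_round_trip_at_feasible_point(self, small_kernel):
        rng = np.random.default_rng(11)
        n = small_kernel.shape[1]
        B = rng.normal(size=(n, 3))
        model = InversionModel(kernel=small_kernel,
                               s=rng.normal(size=small_kernel.shape[0]),
                               lambda1=0.1, lambda2=0.1,
                               dictionary=B, nonneg_c=False)
        problem = split_dictionary_problem(model)
        mA, nA = problem.shape
        x = np.abs(rng.normal(size=nA))
        x[-n:] = B @ (x[:3] - x[3:6])  # consistent f = B c
        r = (problem.b - problem.matvec(x)) / problem.d2
        np.testing.assert_allclose(problem.matvec(x) + problem.d2 * r,
                                   problem.b, atol=1e-12)

    def test_sign_splitting_recovers_negative_coefficient(self):
        """A dictionary atom whose optimal weight is negative appears in c2."""
        tg = si.build_time_grid(1.0, 30)
        t2g = si.build_t2_grid(1.0, 100.0, 10)
        K = si.build_kernel(tg, t2g)
        j = np.arange(10)
        # wide hump minus a narrow dip at the same center stays non-negative
        B = np.column_stack([np.exp(-0.5 * (j - 5) ** 2 / 8.0),
                             np.exp(-0.5 * (j - 5) ** 2 / 1.0)])
        c_true = np.array([1.0, -0.3])
        f_true = B @ c_true
        assert np.all(f_true >= 0)
        s = K.matrix @ f_true
        model = InversionModel(kernel=K, s=s, lambda1=1e-6, lambda2=1e-6,
                               dictionary=B, nonneg_c=False)
        spec = solve_inversion(model)
        # independent check: L-BFGS-B on the same split objective
        import scipy.optimize

        def obj(z):
            c = z[:2] - z[2:4]
            r = K.matrix @ (B @ c) - s
            return 0.5 * r @ r + 1e-6 * z.sum() + 0.5e-6 * (c @ c)

        res = scipy.optimize.minimize(obj, np.full(4, 0.5), method="L-BFGS-B",
                                      bounds=[(0, None)] * 4,
                                      options={"ftol": 1e-15, "gtol": 1e-12})
        c_ref = res.x[:2] - res.x[2:4]
        assert spec.coefficients[1] < -0.05  # negative weight recovered
        np.testing.assert_allclose(spec.coefficients, c_ref, atol=5e-3)


class TestInteriorPointCore:
    def test_unconstrained_quadratic_matches_closed_form(self):
        rng = np.random.default_rng(4)
        m, n = 8, 5
        A = rng.normal(size=(m, n))
        b = rng.normal(size=m)
        q = rng.uniform(0.5, 2.0, size=n)
        d1 = rng.uniform(0.1, 1.0, size=n)
        d2 = rng.uniform(0.5, 2.0, size=m)

        def phi(x):
            return 0.5 * float(x @ (q * x)), q * x, q

        problem = InteriorPointProblem(A=A, b=b, l=np.full(n, -np.inf),
                                       u=np.full(n, np.inf), d1=d1, d2=d2,
                                       phi=phi)
        sol = interior_point_solve(problem, SolverOptions(tol=1e-12))
        H = np.diag(q + d1 ** 2) + A.T @ np.diag(1.0 / d2 ** 2) @ A
        x_star = np.linalg.solve(H, A.T @ (b / d2 ** 2))
        assert np.linalg.norm(sol.x - x_star) <= 1e-8 * (1 + np.linalg.norm(x_star))

    def test_three_variable_nnls_matches_enumeration(self, qp_oracle):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 3))
        # target with a negative component forces an active bound
        b = A @ np.array([1.0, -2.0, 0.5])
        d1 = 1e-5
        problem = InteriorPointProblem(A=A, b=b, l=np.zeros(3),
                                       u=np.full(3, np.inf),
                                       d1=np.full(3, d1), d2=np.ones(6))
        sol = interior_point_solve(problem, SolverOptions(tol=1e-10))
        f_star, _ = qp_oracle(A, b, 0.0, d1 ** 2)
        assert np.any(f_star < 1e-10)  # an active bound exists
        np.testing.assert_allclose(sol.x, f_star, atol=1e-6)

    def test_infeasible_start_reaches_feasibility(self, small_kernel):
        model = InversionModel(kernel=small_kernel,
                               s=np.linspace(1, 0.1, small_kernel.shape[0]),
                               lambda1=0.01, lambda2=0.01)
        spec = solve_inversion(model)
        assert spec.primal_infeasibility < 1e-6

    def test_operator_form_matches_dense(self, small_kernel):
        import scipy.sparse.linalg
        model = _toy_model(m=15, n=6, seed=8)
        dense = split_dictionary_problem(model)
        op = InteriorPointProblem(
            A=scipy.sparse.linalg.aslinearoperator(dense.A),
            b=dense.b, l=dense.l, u=dense.u, d1=dense.d1, d2=dense.d2,
            phi=dense.phi)
        x_dense = interior_point_solve(dense).x
        x_op = interior_point_solve(op).x
        np.testing.assert_allclose(x_op, x_dense, atol=1e-7)


class TestKKTResidual:
    def test_zero_at_origin_for_zero_data(self, small_kernel):
        model = InversionModel(kernel=small_kernel,
                               s=np.zeros(small_kernel.shape[0]),
                               lambda1=0.3, lambda2=0.1)
        spec = solve_inversion(model)
        assert kkt_residual(spec, model) < 1e-8

    def test_perturbation_increases_residual(self):
        from dataclasses import replace
        model = _toy_model(m=20, n=8, seed=6)
        spec = solve_inversion(model)
        base = kkt_residual(spec, model)
        bumped = spec.values.copy()
        bumped[3] += 0.1
        worse = kkt_residual(replace(spec, values=bumped), model)
        assert worse > base
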