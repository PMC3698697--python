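"""Non-negative L1+L2-regularized inversion via a primal-dual interior method.

The regularized inversion of an echo train ``s`` reads

    minimize_{f, c}  1/2 ||K f - s||_2^2 + lambda1 ||c||_1 + 1/2 lambda2 ||c||_2^2
    subject to       f = B c,  f >= 0,

where ``K`` is the discretized Laplace kernel and ``B`` a sparsifying
dictionary (identity by default, imposing sparsity on the spectrum itself).
The problem is encoded in the structural template

    minimize_{x, r}  phi(x) + 1/2 ||D1 x||^2 + 1/2 ||r||^2
    subject to       A x + D2 r = b,   l <= x <= u,

with separable convex ``phi`` (here linear: the L1 term over sign-split,
non-negative coefficients), and solved by a primal-dual interior-point
method whose per-iteration work is one positive-definite normal-equations
solve in the dual step ``dy``, followed by ``dx = D^2 (A^T dy - w)``.

Conventions
-----------
``lambda2`` multiplies the quadratic penalty directly: the objective term is
``1/2 lambda2 ||c||^2``, realized in the template through D1 = sqrt(lambda2)*I.
Equivalently, the lambda1 = 0 unconstrained problem is exactly Tikhonov
regularization with parameter lambda2 (filter factors sigma^2/(sigma^2 +
lambda2)).  The universal calibration constants in
:mod:`sparseilt.calibration` are defined relative to this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .kernel import LaplaceKernel

__all__ = [
    "InversionModel",
    "InteriorPointProblem",
    "SolverOptions",
    "IPSolution",
    "Spectrum",
    "ConvergenceWarning",
    "solve_inversion",
    "split_dictionary_problem",
    "interior_point_solve",
    "kkt_residual",
]


class ConvergenceWarning(UserWarning):
    """Raised when the interior-point iteration stops short of tolerance."""


@dataclass
class InversionModel:
    """A regularized inversion instance ``(K, B, s, lambda1, lambda2)``.

    ``dictionary=None`` means the identity dictionary (c = f); then the
    non-negativity of f is imposed directly on c and the L1 term reduces to
    ``lambda1 * sum(f)``.  A general n x p ``dictionary`` is handled through
    the sign splitting ``c = c1 - c2`` with ``c1, c2 >= 0`` (or ``c = c1``
    alone when ``nonneg_c`` is set).
    """

    kernel: LaplaceKernel
    s: np.ndarray
    lambda1: float
    lambda2: float
    dictionary: np.ndarray | None = None
    nonneg_c: bool = True

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        m, n = self.kernel.shape
        if self.s.shape != (m,):
            raise ValueError(f"s must have length {m}, got shape {self.s.shape}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.dictionary is not None:
            B = np.asarray(self.dictionary, dtype=float)
            if B.ndim != 2 or B.shape[0] != n:
                raise ValueError(f"dictionary must be {n} x p, got {B.shape}")
            self.dictionary = B

    @property
    def n_atoms(self) -> int:
        return self.kernel.shape[1] if self.dictionary is None else self.dictionary.shape[1]


@dataclass
class InteriorPointProblem:
    """A problem instance in the structural interior-point template.

    ``A`` may be a dense array or any object providing ``matvec``/``rmatvec``
    (a :class:`scipy.sparse.linalg.LinearOperator`); with an operator the
    normal equations are solved iteratively (conjugate gradients) instead of
    by dense Cholesky factorization.

    ``phi`` maps x to ``(value, gradient, diagonal Hessian)`` and must be
    separable convex on ``l <= x <= u``.
    """

    A: object
    b: np.ndarray
    l: np.ndarray
    u: np.ndarray
    d1: np.ndarray  # diagonal of D1 (primal regularization), > 0
    d2: np.ndarray  # diagonal of D2 (residual scaling), > 0
    phi: object = None  # callable x -> (val, grad, hess_diag); None = zero
    delta1: float = 1e-4
    delta2: float = 1e-4

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        m = self.b.size
        n = self.l.size if hasattr(self.l, "size") else len(self.l)
        self.l = np.broadcast_to(np.asarray(self.l, dtype=float), (n,)).copy()
        self.u = np.broadcast_to(np.asarray(self.u, dtype=float), (n,)).copy()
        self.d1 = np.broadcast_to(np.asarray(self.d1, dtype=float), (n,)).copy()
        self.d2 = np.broadcast_to(np.asarray(self.d2, dtype=float), (m,)).copy()
        if np.any(self.l > self.u):
            raise ValueError("lower bounds exceed upper bounds")
        if np.any(self.d1 <= 0) or np.any(self.d2 <= 0):
            raise ValueError("D1 and D2 diagonals must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.b.size, self.l.size

    def matvec(self, v: np.ndarray) -> np.ndarray:
        if isinstance(self.A, np.ndarray):
            return self.A @ v
        return self.A.matvec(v)

    def rmatvec(self, w: np.ndarray) -> np.ndarray:
        if isinstance(self.A, np.ndarray):
            return self.A.T @ w
        return self.A.rmatvec(w)

    def phi_eval(self, x: np.ndarray):
        if self.phi is None:
            return 0.0, np.zeros_like(x), np.zeros_like(x)
        return self.phi(x)


@dataclass
class SolverOptions:
    """Interior-point controls.

    ``tol`` bounds the relative primal infeasibility, dual infeasibility and
    mean complementarity at exit.  The fraction-to-boundary factor keeps
    iterates strictly interior; ``mehrotra`` switches on a predictor-corrector
    step (plain path-following with centering factor ``sigma`` is the default).
    """

    tol: float = 1e-8
    max_iter: int = 100
    sigma: float = 0.1
    boundary_frac: float = 0.99
    mehrotra: bool = False
    verbose: bool = False


@dataclass
class IPSolution:
    x: np.ndarray
    y: np.ndarray
    z_lower: np.ndarray
    z_upper: np.ndarray
    iterations: int
    primal_infeasibility: float
    dual_infeasibility: float
    complementarity_gap: float
    objective: float
    converged: bool
    gap_history: list = field(default_factory=list)


@dataclass
class Spectrum:
    """An inverted relaxation-time distribution with solver diagnostics."""

    values: np.ndarray          # f on the kernel's T2 grid
    coefficients: np.ndarray    # c in dictionary space (= f when B = I)
    residual: np.ndarray        # s - K f
    kernel: LaplaceKernel
    iterations: int = 0
    primal_infeasibility: float = np.nan
    dual_infeasibility: float = np.nan
    complementarity_gap: float = np.nan
    objective: float = np.nan
    converged: bool = True
    gap_history: list = field(default_factory=list)

    @property
    def t2(self) -> np.ndarray:
        return self.kernel.col_constants.constants


class _LinearPhi:
    """Separable linear objective term ``g . x`` (zero Hessian)."""

    def __init__(self, g: np.ndarray):
        self.g = np.asarray(g, dtype=float)

    def __call__(self, x: np.ndarray):
        return float(self.g @ x), self.g, np.zeros_like(x)


def split_dictionary_problem(model: InversionModel) -> InteriorPointProblem:
    """Encode the regularized inversion in the interior-point template.

    Identity dictionary with non-negative coefficients: variables are
    ``x = c = f >= 0`` (no sign doubling), A = K, b = s, the L1 term is the
    linear form ``lambda1 * sum(x)`` and D1 = lambda2 * I.

    General dictionary: variables are ``(c1, c2, f)`` (or ``(c1, f)`` when
    ``nonneg_c``), with the data rows ``K B (c1 - c2) + r = s`` scaled by
    D2 = I and auxiliary rows ``B (c1 - c2) - f ~ 0`` held near-exactly by
    the small residual scaling D2 = delta2; ``f >= 0`` is a plain bound.
    """
    K = model.kernel.matrix
    m, n = K.shape
    lam1, lam2 = model.lambda1, model.lambda2
    delta1 = 1e-4
    delta2 = 1e-4
    # D1 = sqrt(lambda2) gives the quadratic term 1/2 lambda2 ||c||^2 exactly,
    # so the lambda1 = 0 solution is the exact Tikhonov solution with
    # parameter lambda2; delta1 only guards the unregularized case.
    d1_c = np.sqrt(lam2) if lam2 > 0 else delta1

    if model.dictionary is None:
        if not model.nonneg_c:
            raise ValueError("identity dictionary requires non-negative coefficients")
        return InteriorPointProblem(
            A=K, b=model.s.copy(),
            l=np.zeros(n), u=np.full(n, np.inf),
            d1=np.full(n, d1_c), d2=np.ones(m),
            phi=_LinearPhi(np.full(n, lam1)),
            delta1=delta1, delta2=delta2,
        )

    B = model.dictionary
    p = B.shape[1]
    KB = K @ B
    if model.nonneg_c:
        # x = (c1, f): [KB, 0] x + r = s ; [B, -I] x + delta2 r2 = 0
        A = np.block([[KB, np.zeros((m, n))], [B, -np.eye(n)]])
        g = np.concatenate([np.full(p, lam1), np.zeros(n)])
        d1 = np.concatenate([np.full(p, d1_c), np.full(n, delta1)])
        l = np.zeros(p + n)
        u = np.full(p + n, np.inf)
    else:
        # x = (c1, c2, f), c = c1 - c2
        A = np.block([[KB, -KB, np.zeros((m, n))], [B, -B, -np.eye(n)]])
        g = np.concatenate([np.full(2 * p, lam1), np.zeros(n)])
        d1 = np.concatenate([np.full(2 * p, d1_c), np.full(n, delta1)])
        l = np.zeros(2 * p + n)
        u = np.full(2 * p + n, np.inf)
    b = np.concatenate([model.s, np.zeros(n)])
    d2 = np.concatenate([np.ones(m), np.full(n, delta2)])
    return InteriorPointProblem(A=A, b=b, l=l, u=u, d1=d1, d2=d2,
                                phi=_LinearPhi(g), delta1=delta1, delta2=delta2)


def _objective(problem: InteriorPointProblem, x: np.ndarray, y: np.ndarray) -> float:
    val, _, _ = problem.phi_eval(x)
    r = problem.d2 * y
    return val + 0.5 * float(np.sum((problem.d1 * x) ** 2)) + 0.5 * float(r @ r)


def interior_point_solve(problem: InteriorPointProblem,
                         options: SolverOptions | None = None) -> IPSolution:
    """Primal-dual interior-point solve of the structural template.

    Follows the central path of the barrier subproblems: each iteration
    solves the positive-definite system ``(A D^2 A^T + D2^2) dy = rhs`` and
    back-substitutes ``dx = D^2 (A^T dy + w)``, then takes damped steps with
    a fraction-to-boundary rule so iterates remain strictly interior.
    The residual variable is carried implicitly through ``r = D2 y``.
    """
    opts = options or SolverOptions()
    m, n = problem.shape
    l, u = problem.l, problem.u
    d1sq = problem.d1 ** 2
    d2sq = problem.d2 ** 2
    has_lo = np.isfinite(l)
    has_up = np.isfinite(u)
    n_bounded = int(has_lo.sum() + has_up.sum())
    dense = isinstance(problem.A, np.ndarray)

    # Starting point: strictly interior, deterministic.  Finite two-sided
    # bounds start at their midpoint; one-sided bounds at unit offset.
    x = np.zeros(n)
    both = has_lo & has_up
    x[both] = 0.5 * (l[both] + u[both])
    x[has_lo & ~has_up] = l[has_lo & ~has_up] + 1.0
    x[~has_lo & has_up] = u[~has_lo & has_up] - 1.0
    y = np.zeros(m)
    z1 = np.where(has_lo, 1.0, 0.0)
    z2 = np.where(has_up, 1.0, 0.0)

    def residuals(x, y, z1, z2):
        _, g, _ = problem.phi_eval(x)
        F1 = problem.matvec(x) + d2sq * y - problem.b
        F2 = g + d1sq * x - problem.rmatvec(y) - z1 + z2
        return F1, F2, g

    gap_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        F1, F2, g = residuals(x, y, z1, z2)
        x1 = np.where(has_lo, x - l, 1.0)
        x2 = np.where(has_up, u - x, 1.0)
        comp = float(np.sum(x1[has_lo] * z1[has_lo]) + np.sum(x2[has_up] * z2[has_up]))
        mu_avg = comp / max(n_bounded, 1)
        obj = _objective(problem, x, y)

        pinf = np.max(np.abs(F1)) / (1.0 + np.max(np.abs(problem.b), initial=0.0))
        dscale = 1.0 + float(np.max(np.abs(g + d1sq * x), initial=0.0)) \
                     + float(np.max(np.abs(y), initial=0.0))
        dinf = np.max(np.abs(F2)) / dscale
        gap = mu_avg / (1.0 + abs(obj)) if n_bounded else 0.0
        gap_history.append(gap)
        if opts.verbose:
            print(f"  it {it:3d}  pinf {pinf:9.2e}  dinf {dinf:9.2e}  gap {gap:9.2e}")
        if pinf <= opts.tol and dinf <= opts.tol and gap <= opts.tol:
            converged = True
            break

        _, _, h = problem.phi_eval(x)
        hbar = h + d1sq \
            + np.where(has_lo, z1 / np.maximum(x1, 1e-300), 0.0) \
            + np.where(has_up, z2 / np.maximum(x2, 1e-300), 0.0)
        dsq = 1.0 / hbar

        def newton_step(mu, dx_aff=None, dz1_aff=None, dz2_aff=None):
            # complementarity targets (with optional Mehrotra correction)
            c1 = np.where(has_lo, mu - x1 * z1, 0.0)
            c2 = np.where(has_up, mu - x2 * z2, 0.0)
            if dx_aff is not None:
                c1 = np.where(has_lo, c1 - dx_aff * dz1_aff, 0.0)
                c2 = np.where(has_up, c2 + dx_aff * dz2_aff, 0.0)
            w = -F2 + np.where(has_lo, c1 / np.maximum(x1, 1e-300), 0.0) \
                    - np.where(has_up, c2 / np.maximum(x2, 1e-300), 0.0)
            rhs = -F1 - problem.matvec(dsq * w)
            if dense:
                Adsq = problem.A * dsq  # scales columns
                Msys = Adsq @ problem.A.T + np.diag(d2sq)
                cho = scipy.linalg.cho_factor(Msys, check_finite=False)
                dy = scipy.linalg.cho_solve(cho, rhs, check_finite=False)
            else:
                def mv(v):
                    return problem.matvec(dsq * problem.rmatvec(v)) + d2sq * v
                op = scipy.sparse.linalg.LinearOperator((m, m), matvec=mv)
                dy, info = scipy.sparse.linalg.cg(op, rhs, rtol=1e-12, atol=0.0,
                                                  maxiter=10 * m)
                if info != 0:
                    raise np.linalg.LinAlgError("normal-equations CG did not converge")
            dx = dsq * (problem.rmatvec(dy) + w)
            dz1 = np.where(has_lo, (c1 - z1 * dx) / np.maximum(x1, 1e-300), 0.0)
            dz2 = np.where(has_up, (c2 + z2 * dx) / np.maximum(x2, 1e-300), 0.0)
            return dx, dy, dz1, dz2

        def max_steps(dx, dz1, dz2):
            with np.errstate(divide="ignore", invalid="ignore"):
                ap = 1.0
                lo_hit = has_lo & (dx < 0)
                up_hit = has_up & (dx > 0)
                if np.any(lo_hit):
                    ap = min(ap, float(np.min(x1[lo_hit] / -dx[lo_hit])))
                if np.any(up_hit):
                    ap = min(ap, float(np.min(x2[up_hit] / dx[up_hit])))
                ad = 1.0
                z1_hit = has_lo & (dz1 < 0)
                z2_hit = has_up & (dz2 < 0)
                if np.any(z1_hit):
                    ad = min(ad, float(np.min(z1[z1_hit] / -dz1[z1_hit])))
                if np.any(z2_hit):
                    ad = min(ad, float(np.min(z2[z2_hit] / -dz2[z2_hit])))
            return ap, ad

        try:
            if opts.mehrotra and n_bounded:
                dx_a, dy_a, dz1_a, dz2_a = newton_step(0.0)
                ap_a, ad_a = max_steps(dx_a, dz1_a, dz2_a)
                x1_a = x1 + min(1.0, opts.boundary_frac * ap_a) * np.where(has_lo, dx_a, 0.0)
                x2_a = x2 - min(1.0, opts.boundary_frac * ap_a) * np.where(has_up, dx_a, 0.0)
                z1_a = z1 + min(1.0, opts.boundary_frac * ad_a) * dz1_a
                z2_a = z2 + min(1.0, opts.boundary_frac * ad_a) * dz2_a
                comp_a = float(np.sum(x1_a[has_lo] * z1_a[has_lo])
                               + np.sum(x2_a[has_up] * z2_a[has_up]))
                sig = min(1.0, max(1e-4, (comp_a / max(comp, 1e-300)) ** 3))
                dx, dy, dz1, dz2 = newton_step(sig * mu_avg, dx_a, dz1_a, dz2_a)
            else:
                dx, dy, dz1, dz2 = newton_step(opts.sigma * mu_avg)
        except np.linalg.LinAlgError:
            break  # severe ill-conditioning: return last iterate

        ap, ad = max_steps(dx, dz1, dz2)
        ap = min(1.0, opts.boundary_frac * ap)
        ad = min(1.0, opts.boundary_frac * ad)
        if n_bounded and max(ap, ad) < 1e-12:
            break  # stalled
        x = x + ap * dx
        y = y + ad * dy
        z1 = np.where(has_lo, z1 + ad * dz1, 0.0)
        z2 = np.where(has_up, z2 + ad * dz2, 0.0)

    F1, F2, g = residuals(x, y, z1, z2)
    x1 = np.where(has_lo, x - l, 1.0)
    x2 = np.where(has_up, u - x, 1.0)
    comp = float(np.sum(x1[has_lo] * z1[has_lo]) + np.sum(x2[has_up] * z2[has_up]))
    obj = _objective(problem, x, y)
    pinf = np.max(np.abs(F1)) / (1.0 + np.max(np.abs(problem.b), initial=0.0))
    dscale = 1.0 + float(np.max(np.abs(g + d1sq * x), initial=0.0)) \
                 + float(np.max(np.abs(y), initial=0.0))
    dinf = np.max(np.abs(F2)) / dscale
    gap = comp / max(n_bounded, 1) / (1.0 + abs(obj)) if n_bounded else 0.0
    return IPSolution(x=x, y=y, z_lower=z1, z_upper=z2, iterations=it,
                      primal_infeasibility=float(pinf),
                      dual_infeasibility=float(dinf),
                      complementarity_gap=float(gap),
                      objective=obj, converged=converged,
                      gap_history=gap_history)


def solve_inversion(model: InversionModel,
                    options: SolverOptions | None = None) -> Spectrum:
    """Invert an echo train into a non-negative relaxation-time distribution.

    Returns a :class:`Spectrum` with the distribution ``f`` (>= 0 to bound
    tolerance), the dictionary coefficients, the data residual ``s - K f``
    and interior-point diagnostics.  If the iteration limit is reached
    without convergence a :class:`ConvergenceWarning` is emitted and the
    partial solution is returned with ``converged=False``.
    """
    problem = split_dictionary_problem(model)
    sol = interior_point_solve(problem, options)
    if not sol.converged:
        warnings.warn(
            f"interior-point solve stopped after {sol.iterations} iterations "
            f"(pinf={sol.primal_infeasibility:.2e}, "
            f"dinf={sol.dual_infeasibility:.2e}, "
            f"gap={sol.complementarity_gap:.2e})", ConvergenceWarning)
    n = model.kernel.shape[1]
    if model.dictionary is None:
        c = sol.x
        f = c
    else:
        p = model.dictionary.shape[1]
        if model.nonneg_c:
            c = sol.x[:p]
        else:
            c = sol.x[:p] - sol.x[p:2 * p]
        f = sol.x[-n:]
    residual = model.s - model.kernel.matrix @ f
    return Spectrum(values=f, coefficients=c, residual=residual,
                    kernel=model.kernel, iterations=sol.iterations,
                    primal_infeasibility=sol.primal_infeasibility,
                    dual_infeasibility=sol.dual_infeasibility,
                    complementarity_gap=sol.complementarity_gap,
                    objective=sol.objective, converged=sol.converged,
                    gap_history=sol.gap_history)


def kkt_residual(spec: Spectrum, model: InversionModel) -> float:
    """First-order optimality violation of a candidate spectrum.

    For the identity-dictionary non-negative problem the stationarity
    residual at f is ``g = K^T (K f - s) + lambda1 + lambda2 f``; at an
    exact optimum ``g >= 0`` and ``g_j f_j = 0`` for every bin.  Returns the
    maximum over bins of ``max(-g_j, |g_j f_j| / (1 + |f_j|))`` — zero at
    the exact optimum, monotone in the size of any perturbation.
    """
    if model.dictionary is not None:
        raise NotImplementedError("KKT residual is defined for the identity dictionary")
    K = model.kernel.matrix
    f = np.asarray(spec.values, dtype=float)
    g = K.T @ (K @ f - model.s) + model.lambda1 + model.lambda2 * f
    comp = np.abs(g * f) / (1.0 + np.abs(f))
    return float(np.max(np.maximum(-g, comp), initial=0.0))
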