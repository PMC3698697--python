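"""Shared fixtures: grids, small random inversion instances, oracles.

The two-peak resolution sweep is expensive (12 separations x 5 seeds x one
interior-point solve each per cell), so its cells are computed once per
session and shared between the property tests and the acceptance tests.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pytest

import sparseilt as si


@pytest.fixture(scope="session")
def t2_grid():
    return si.build_t2_grid()


@pytest.fixture(scope="session")
def small_kernel():
    """A modest 40 x 12 kernel for fast exact-recovery tests."""
    tg = si.build_time_grid(1.0, 40)
    t2g = si.build_t2_grid(1.0, 100.0, 12)
    return si.build_kernel(tg, t2g, normalize=True)


def nonneg_qp_oracle(K: np.ndarray, s: np.ndarray,
                     lam1: float, lam2: float) -> tuple[np.ndarray, float]:
    """Exhaustive active-set oracle for the non-negative inversion objective.

    Minimizes ``1/2 ||K f - s||^2 + lam1 * sum(f) + 1/2 lam2 ||f||^2`` over
    ``f >= 0`` by enumerating every face of the non-negative orthant and
    keeping the best feasible face minimizer.  Exact for lam2 > 0 (strictly
    convex); practical for n <= ~12.
    """
    n = K.shape[1]
    H = K.T @ K + lam2 * np.eye(n)
    g = K.T @ s - lam1

    def objective(f):
        r = K @ f - s
        return 0.5 * r @ r + lam1 * f.sum() + 0.5 * lam2 * f @ f

    best_f, best_obj = np.zeros(n), objective(np.zeros(n))
    for mask in itertools.product((False, True), repeat=n):
        F = np.array(mask)
        if not F.any():
            continue
        f = np.zeros(n)
        try:
            f[F] = np.linalg.solve(H[np.ix_(F, F)], g[F])
        except np.linalg.LinAlgError:
            continue
        if np.any(f < -1e-12):
            continue
        f = np.maximum(f, 0.0)
        obj = objective(f)
        if obj < best_obj:
            best_f, best_obj = f, obj
    return best_f, best_obj


@pytest.fixture(scope="session")
def qp_oracle():
    return nonneg_qp_oracle


def _resolution_cell(width, snr, alpha2):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return si.resolution_limit(width, snr, alpha1=10.0, alpha2=alpha2,
                                   seeds=[0, 1, 2, 3, 4])


@pytest.fixture(scope="session")
def resolution_cells():
    """Lazily computed two-peak resolution cells, shared across tests."""
    cache: dict[tuple, object] = {}

    def get(width, snr, alpha2):
        key = (width, snr, alpha2)
        if key not in cache:
            cache[key] = _resolution_cell(*key)
        return cache[key]

    return get
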