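"""Discretized Laplace kernel for CPMG relaxometry.

The forward model for a CPMG echo train is

    s(t_i) = sum_j f(T_j) * exp(-t_i / T_j) + noise,

a discretized Fredholm integral of the first kind with kernel
K(t, T) = exp(-t/T).  This module builds the acquisition-time grid, the
logarithmically spaced relaxation-time (T2) grid, the kernel matrix K, its
(truncated) singular value decomposition, and the Tikhonov filter factors
w(sigma) = sigma^2 / (sigma^2 + lambda) that connect L2 regularization to
smooth damping of the singular spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeGrid",
    "T2Grid",
    "LaplaceKernel",
    "SVDFactors",
    "build_time_grid",
    "build_t2_grid",
    "build_kernel",
    "svd_compress",
    "tikhonov_weights",
]

#: Default T2 grid, chosen to bracket every relaxation time of practical
#: interest for bench-top CPMG work (roughly 1 ms .. 600 ms) with wide margin.
DEFAULT_T2_MIN = 0.1
DEFAULT_T2_MAX = 10_000.0
DEFAULT_T2_POINTS = 256

#: Default acquisition: 16,384 echoes at 0.1 ms echo spacing (a 1638.4 ms
#: window, long enough for full decay of the slowest components above).
DEFAULT_ECHO_SPACING = 0.1
DEFAULT_N_ECHOES = 16_384


@dataclass(frozen=True)
class TimeGrid:
    """Echo acquisition times ``t_1..t_m`` in milliseconds."""

    times: np.ndarray
    echo_spacing: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(t <= 0):
            raise ValueError("acquisition times must be strictly positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def m(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class T2Grid:
    """Logarithmically spaced relaxation-time constants in milliseconds."""

    constants: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.constants, dtype=float)
        if T.ndim != 1 or T.size < 2:
            raise ValueError("need at least two T2 constants")
        if np.any(T <= 0) or np.any(np.diff(T) <= 0):
            raise ValueError("T2 constants must be positive and strictly increasing")
        object.__setattr__(self, "constants", T)

    @property
    def n(self) -> int:
        return self.constants.size


@dataclass(frozen=True)
class LaplaceKernel:
    """The m x n matrix ``K[i, j] = exp(-t_i / T_j)`` (optionally rescaled).

    ``scale`` is the pre-normalization maximum entry; after normalization the
    maximum entry is exactly 1, so amplitudes can be un-scaled by multiplying
    a fitted spectrum's predicted signal by ``scale``.

    ``row_times`` is ``None`` for spectrally reduced systems whose rows are
    orthogonal combinations of echoes rather than echo times.
    """

    matrix: np.ndarray
    row_times: TimeGrid | None
    col_constants: T2Grid
    scale: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass(frozen=True)
class SVDFactors:
    """Thin SVD ``K = U diag(s) V^T`` with the first ``rank`` components retained."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ValueError("singular values must be non-negative and non-increasing")
        if not 1 <= self.rank <= s.size:
            raise ValueError("rank out of range")

    def condition_number(self) -> float:
        s = self.singular_values
        return float(s[0] / s[-1]) if s[-1] > 0 else np.inf


def build_time_grid(echo_spacing: float = DEFAULT_ECHO_SPACING,
                    m: int = DEFAULT_N_ECHOES) -> TimeGrid:
    """Uniform echo times ``i * echo_spacing`` for i = 1..m (milliseconds)."""
    if echo_spacing <= 0:
        raise ValueError(f"echo_spacing must be positive, got {echo_spacing}")
    if m < 1:
        raise ValueError(f"echo count must be >= 1, got {m}")
    times = echo_spacing * np.arange(1, m + 1, dtype=float)
    return TimeGrid(times=times, echo_spacing=float(echo_spacing))


def build_t2_grid(t2_min: float = DEFAULT_T2_MIN,
                  t2_max: float = DEFAULT_T2_MAX,
                  n: int = DEFAULT_T2_POINTS) -> T2Grid:
    """``n`` log-spaced T2 constants with endpoints exactly t2_min and t2_max."""
    if not (0 < t2_min < t2_max):
        raise ValueError(f"need 0 < t2_min < t2_max, got ({t2_min}, {t2_max})")
    if n < 2:
        raise ValueError(f"grid size must be >= 2, got {n}")
    T = np.geomspace(t2_min, t2_max, n)
    T[0], T[-1] = t2_min, t2_max  # exact endpoints
    return T2Grid(constants=T)


def build_kernel(tg: TimeGrid, t2g: T2Grid, normalize: bool = True) -> LaplaceKernel:
    """Assemble ``K[i, j] = exp(-t_i / T_j)``.

    With ``normalize`` the matrix is divided by its maximum entry so that
    ``max K[i, j] = 1``; the divisor is retained in ``scale``.
    """
    M = np.exp(-np.outer(tg.times, 1.0 / t2g.constants))
    scale = 1.0
    if normalize:
        scale = float(M.max())
        M = M / scale
    return LaplaceKernel(matrix=M, row_times=tg, col_constants=t2g, scale=scale)


def svd_compress(K: LaplaceKernel, r: int) -> tuple[SVDFactors, LaplaceKernel]:
    """Rank-r truncated SVD of the kernel.

    Returns the retained factors and the best rank-r approximation of K
    (Eckart-Young: its spectral-norm error equals the (r+1)-th singular value).
    """
    n = K.shape[1]
    if not 1 <= r <= n:
        raise ValueError(f"rank r must satisfy 1 <= r <= {n}, got {r}")
    U, s, Vt = np.linalg.svd(K.matrix, full_matrices=False)
    factors = SVDFactors(U=U[:, :r], singular_values=s[:r], V=Vt[:r].T, rank=r)
    Kr = (U[:, :r] * s[:r]) @ Vt[:r]
    compressed = LaplaceKernel(matrix=Kr, row_times=K.row_times,
                               col_constants=K.col_constants, scale=K.scale)
    return factors, compressed


def tikhonov_weights(singular_values: np.ndarray, lam: float) -> np.ndarray:
    """Filter factors ``w(sigma) = sigma^2 / (sigma^2 + lam)``.

    L2 (Tikhonov) regularization of the least-squares inversion is equivalent
    to multiplying each SVD coefficient by these weights: values lie in
    [0, 1] and are non-decreasing in sigma.  The 0/0 case (sigma = lam = 0)
    is defined as 0 (full damping of a null direction).
    """
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    s2 = s * s
    denom = s2 + lam
    with np.errstate(invalid="ignore"):
        w = np.where(denom > 0, s2 / np.where(denom > 0, denom, 1.0), 0.0)
    return w
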