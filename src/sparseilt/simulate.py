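"""Synthetic CPMG echo trains with known relaxation-time distributions.

Ground-truth spectra are sums of Gaussian peaks placed in *index* space on
the logarithmic T2 grid (widths are expressed in grid bins), which keeps the
peak shape scale-free across the decades of the grid.  Clean echo trains are
the exact multiexponential forward model ``s_i = sum_j f_j exp(-t_i/T_j)``;
noise is additive white Gaussian with standard deviation ``max(s)/SNR``.

Named signal constructors reproduce the standard three-peak test signals
(five variants whose outer peaks progressively approach the fixed middle
peak at 21.54 ms), the broad single-peak signal typical of an oil-sample L2
solution, and the twelve-member two-peak series used for resolution-limit
sweeps (fixed peak at 81.54 ms, moving peak from 27.53 to 71.58 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .kernel import (T2Grid, TimeGrid, build_t2_grid, build_time_grid,
                     DEFAULT_ECHO_SPACING, DEFAULT_N_ECHOES)

__all__ = [
    "SyntheticSpec",
    "EchoTrain",
    "NARROW_SIGNAL_CENTERS",
    "TWO_PEAK_FIXED",
    "TWO_PEAK_MOVING",
    "make_spectrum",
    "forward_simulate",
    "add_noise",
    "narrow_signal",
    "two_peak_series",
    "broad_peak_spec",
    "simulate_echo_train",
]

#: Intrinsic T2 centers (ms) of the five three-peak narrow test signals.
NARROW_SIGNAL_CENTERS: dict[int, tuple[float, float, float]] = {
    1: (1.44, 21.54, 323.45),
    2: (2.25, 21.54, 205.93),
    3: (3.54, 21.54, 131.11),
    4: (5.56, 21.54, 83.48),
    5: (8.73, 21.54, 53.15),
}

#: Two-peak resolution series: fixed peak (ms) and moving-peak positions (ms),
#: ordered from the farthest separation to the closest.
TWO_PEAK_FIXED = 81.54
TWO_PEAK_MOVING: tuple[float, ...] = (
    27.53, 30.03, 32.75, 35.73, 38.97, 42.51, 46.36, 50.57, 55.16, 60.16,
    65.62, 71.58,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parametric description of a ground-truth spectrum.

    ``width_std`` is the Gaussian standard deviation in grid-index units on
    the (log-spaced) T2 grid; ``snr`` may be ``math.inf`` for noise-free
    trains.
    """

    centers: tuple[float, ...]
    amplitudes: tuple[float, ...]
    width_std: float
    snr: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.amplitudes):
            raise ValueError("centers and amplitudes must have equal length")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be positive")
        if self.width_std <= 0:
            raise ValueError("width_std must be positive")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (math.inf for noise-free)")


@dataclass(frozen=True)
class EchoTrain:
    """A (simulated or measured) CPMG decay with its noise component."""

    times: TimeGrid
    amplitudes: np.ndarray
    noise_component: np.ndarray = None
    realized_snr: float = math.nan

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != self.times.times.shape:
            raise ValueError("amplitudes must match the time grid")
        object.__setattr__(self, "amplitudes", amps)
        noise = self.noise_component
        noise = np.zeros_like(amps) if noise is None else np.asarray(noise, dtype=float)
        object.__setattr__(self, "noise_component", noise)

    @property
    def m(self) -> int:
        return self.times.m

    @property
    def clean(self) -> np.ndarray:
        return self.amplitudes - self.noise_component


def make_spectrum(spec: SyntheticSpec, grid: T2Grid) -> np.ndarray:
    """Ground-truth distribution: Gaussian peaks in index space.

    ``f_j = sum_k a_k exp(-(j - j_k)^2 / (2 width_std^2))`` where ``j_k`` is
    the grid index nearest ``center_k`` in log(T2) (the natural metric on a
    log-spaced grid).
    """
    T = grid.constants
    logT = np.log(T)
    f = np.zeros(grid.n)
    j = np.arange(grid.n, dtype=float)
    for center, amp in zip(spec.centers, spec.amplitudes):
        if not (T[0] <= center <= T[-1]):
            raise ValueError(f"peak center {center} ms outside grid "
                             f"[{T[0]}, {T[-1]}] ms")
        jk = int(np.argmin(np.abs(logT - math.log(center))))
        f += amp * np.exp(-((j - jk) ** 2) / (2.0 * spec.width_std ** 2))
    return f


def forward_simulate(f: np.ndarray, tg: TimeGrid, t2g: T2Grid) -> EchoTrain:
    """Clean echo train ``s_i = sum_j f_j exp(-t_i / T_j)``.

    Uses the physical (unnormalized) kernel, so amplitudes are in the same
    units as ``f`` summed over bins.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (t2g.n,):
        raise ValueError(f"f must have length {t2g.n}")
    s = np.exp(-np.outer(tg.times, 1.0 / t2g.constants)) @ f
    return EchoTrain(times=tg, amplitudes=s, realized_snr=math.inf)


def add_noise(clean: EchoTrain, target_snr: float, seed: int) -> EchoTrain:
    """Add white Gaussian noise of standard deviation ``max(clean)/SNR``.

    ``target_snr = math.inf`` returns the train unchanged.  The realized SNR
    is re-estimated from the noisy train with :func:`sparseilt.metrics.estimate_snr`.
    """
    if not (target_snr > 0):
        raise ValueError(f"target SNR must be positive, got {target_snr}")
    if math.isinf(target_snr):
        return clean
    from .metrics import estimate_snr  # local import to avoid a cycle
    rng = np.random.default_rng(seed)
    sigma = float(np.max(clean.amplitudes)) / target_snr
    noise = rng.normal(0.0, sigma, size=clean.m)
    noisy = EchoTrain(times=clean.times,
                      amplitudes=clean.amplitudes + noise,
                      noise_component=clean.noise_component + noise)
    realized = estimate_snr(noisy, warn=False)
    return replace(noisy, realized_snr=realized)


def narrow_signal(index: int, width_std: float = 2.0,
                  snr: float = 10_000.0, seed: int = 0) -> SyntheticSpec:
    """One of the five standard three-peak narrow test signals (equal amplitudes)."""
    if index not in NARROW_SIGNAL_CENTERS:
        raise ValueError(f"signal index must be 1..5, got {index}")
    centers = NARROW_SIGNAL_CENTERS[index]
    return SyntheticSpec(centers=centers, amplitudes=(1.0,) * len(centers),
                         width_std=width_std, snr=snr, seed=seed)


def two_peak_series(width_std: float, snr: float, seed: int) -> list[SyntheticSpec]:
    """The twelve two-peak resolution specs, farthest separation first.

    Every member keeps the fixed peak at 81.54 ms and places the moving peak
    at one listed position, with equal amplitudes.  Member seeds are derived
    deterministically from ``seed`` so each separation draws independent noise.
    """
    if width_std <= 0 or not (snr > 0):
        raise ValueError("width_std and snr must be positive")
    return [
        SyntheticSpec(centers=(moving, TWO_PEAK_FIXED), amplitudes=(1.0, 1.0),
                      width_std=width_std, snr=snr, seed=seed * 100 + i)
        for i, moving in enumerate(TWO_PEAK_MOVING)
    ]


def broad_peak_spec(snr: float, seed: int = 0, center: float = 150.0,
                    width_std: float = 20.0) -> SyntheticSpec:
    """A single wide bump emulating a typical L2 solution of an oil sample.

    Synthetic stand-in: the empirical broad distribution it emulates is not
    tabulated anywhere, so a single wide Gaussian (in log-index space, hence
    log-normal-like in T2) centered near 150 ms is used; parameters are
    configurable.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    return SyntheticSpec(centers=(center,), amplitudes=(1.0,),
                         width_std=width_std, snr=snr, seed=seed)


def simulate_echo_train(spec: SyntheticSpec, t2g: T2Grid | None = None,
                        echo_spacing: float = DEFAULT_ECHO_SPACING,
                        m: int = DEFAULT_N_ECHOES) -> tuple[EchoTrain, np.ndarray]:
    """Spectrum -> clean forward model -> noise, in one step.

    Returns the (noisy) echo train and the ground-truth distribution on the
    T2 grid.
    """
    t2g = t2g or build_t2_grid()
    tg = build_time_grid(echo_spacing, m)
    f = make_spectrum(spec, t2g)
    clean = forward_simulate(f, tg, t2g)
    return add_noise(clean, spec.snr, spec.seed), f
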