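# Methods

## The inverse problem

A CPMG echo train is modeled as a discrete Fredholm integral of the first
kind, `s = K f + e`, with kernel `K[i, j] = exp(-t_i / T_j)` evaluated on
the acquisition times `t_i = i * dt` and a logarithmically spaced grid of
relaxation times `T_j`.  The kernel's singular values decay roughly
geometrically; on the default grids the condition number exceeds 1e6 within
the first few dozen modes, so unregularized least squares amplifies noise
proportionally to `1/sigma_j` and is useless in practice.  Two classical
stabilizations are provided as building blocks: truncated SVD (sharp
spectral cut-off, Eckart–Young optimal) and Tikhonov damping, whose filter
factors `w(sigma) = sigma^2 / (sigma^2 + lambda)` the L2 path of the solver
reproduces exactly.

## The regularized model and its conventions

The production model is

```
minimize   1/2 ||K f - s||^2  +  lambda1 ||c||_1  +  1/2 lambda2 ||c||^2
subject to f = B c,   f >= 0
```

with the identity dictionary `B = I` by default (sparsity imposed on the
spectrum itself; appropriate for well-localized peaks).  Two conventions
deserve emphasis because the calibration constants are defined relative to
them:

- **lambda2 is a direct Tikhonov weight.**  It multiplies `1/2 ||c||^2`
  as-is; in the interior-point template it enters through
  `D1 = sqrt(lambda2) * I`.  The alternative reading (lambda2 entering
  squared) makes the L2 term numerically inert at high SNR
  (`lambda2^2 ~ 2.5e-7` at SNR 10,000), which contradicts the observable
  sensitivity of the resolution limit to `alpha2` at high SNR; the direct
  convention reproduces that sensitivity and the reference resolution
  values, so it is adopted.  Under the universal rule all three objective
  terms scale as the square of the signal amplitude, so solutions are
  invariant to rescaling the data.
- **The fit uses the complete echo train.**  Fitting all `m = 16,384`
  acquired echoes (rather than a 256-point logarithmically pruned subset)
  retains the full statistical information of the measurement.  Because the
  least-squares term only touches the data through `range(K)`, the tall
  system is first reduced exactly — `K = U S V^T`, fit `(S V^T) f ~ U^T s` —
  which is lossless and leaves an n-by-n solve.  The reduction depends only
  on the grids and is cached across inversions.  Lossy logarithmic pruning
  (subsampling at geometric echo indices, duplicates backfilled with the
  smallest unused indices) remains available in `io_cli.log_prune` and via
  the CLI `--prune` flag for workflows that expect it.

`kkt_residual` provides an implementation-independent optimality check for
the identity-dictionary problem: at an optimum the reduced gradient
`g = K^T(Kf - s) + lambda1 + lambda2 f` must be non-negative with
`g_j f_j = 0` per bin.

## The interior-point solver

Problems are expressed in the structural template

```
minimize  phi(x) + 1/2 ||D1 x||^2 + 1/2 ||r||^2
subject to A x + D2 r = b,   l <= x <= u
```

with separable convex `phi` (linear for the L1 term over sign-split
non-negative coefficients).  The solver follows the central path: the
residual variable is carried implicitly through `r = D2 y`, and each
iteration solves the positive-definite system
`(A D^2 A^T + D2^2) dy = rhs` (dense Cholesky when `A` is an array;
conjugate gradients on operator input) and back-substitutes
`dx = D^2 (A^T dy + w)`.  Numerical choices:

- convergence when relative primal infeasibility, dual infeasibility and
  mean complementarity all fall below `tol = 1e-8`; iteration cap 100
  (typical runs converge in 25–50 iterations);
- plain path-following with centering factor 0.1 and fraction-to-boundary
  0.99 by default; a Mehrotra predictor-corrector is available behind the
  `mehrotra` option;
- deterministic start: midpoints of finite bound intervals, unit offset
  from one-sided bounds, `y = 0`, unit bound multipliers; no randomness
  anywhere in the solver;
- safeguards `delta1 = delta2 = 1e-4`: `delta1` floors `D1` only when
  `lambda2 = 0` (so the L2-only solution remains the exact Tikhonov
  solution), `delta2` scales the auxiliary constraint rows that tie
  `f = B c` in the general-dictionary case;
- non-convergence returns the last iterate with diagnostics and a
  `ConvergenceWarning` rather than raising.

For a general dictionary the coefficients are sign-split, `c = c1 - c2`
with `c1, c2 >= 0`, the L1 term becomes the linear form
`lambda1 * 1^T (c1 + c2)`, and `f >= 0` is enforced as a plain bound on an
auxiliary block tied to `B(c1 - c2)` by near-exact rows.

## Calibration

`lambda1 = alpha1 * ||s||_inf / SNR` and `lambda2 = alpha2 / SNR`, with
shipped constants `alpha1 = 10`, `alpha2 = 5` — a deliberately conservative
universal pair that stays stable for wide peaks and low SNR at the price of
some broadening; `alpha2 = 0.5` is the documented "less conservative"
alternative for high-SNR data.  The rule is validated down to SNR 150 and
the code warns below that floor.  `grid_search_alphas` reproduces the
calibration procedure itself: inverting simulated signals with known
ground truth over an (alpha1, alpha2) grid, scoring by `||f - x||_2` on the
common 256-point grid, and reporting per-signal minimizers plus the modal
pair.

For real data the SNR is estimated from the train (signal = maximum of an
8-point moving average; noise = RMS of the last 1,024 echoes after removing
their best-fit line — the tail of a long train is pure noise up to a linear
drift).  For simulations the nominal target SNR is used.  A zero-noise tail
returns an infinite-SNR sentinel.

## The synthetic-data generator

Ground-truth spectra are sums of Gaussian peaks in *index* space on the
256-point log grid spanning 0.1–10,000 ms (width is scale-free across the
grid's five decades; one bin is a factor 1.046 in T2).  Echo trains use
`dt = 0.1` ms and `m = 16,384` echoes — a 1638 ms window that covers every
simulated relaxation time with margin.  Noise is additive white Gaussian
with standard deviation `max(s)/SNR`, the standard assumption for bench-top
CPMG noise, seeded and bit-reproducible.  Named constructors provide:

- the five three-peak narrow signals (outer peaks approaching the fixed
  21.54 ms middle peak; signal 5's adjacent ratios are 2.47);
- the twelve-member two-peak resolution series (fixed peak 81.54 ms, moving
  peak from 27.53 to 71.58 ms, equal amplitudes);
- a broad single bump (Gaussian of std 20 bins, i.e. log-normal-like in T2,
  centered at 150 ms) emulating the *character* of a typical L2 oil-sample
  solution — a synthetic stand-in, since no such empirical distribution is
  tabulated; its parameters are configurable.

What the generator does **not** emulate: phase errors, receiver offset
drift, B1 inhomogeneity, temperature drift, correlated or Rician noise,
amplitude differences between peaks.  Passing tests therefore demonstrate
correctness of the inversion machinery under ideal white-noise conditions,
not robustness to instrument artifacts.

## Resolution and stability procedures

The resolution sweep walks the two-peak series from the farthest separation
toward the closest.  Each separation is simulated and inverted under five
seeds; it counts as resolved when the majority of seeds yield at least two
detected maxima (strict local maxima above 1% of the spectrum maximum,
plateau midpoints, endpoints excluded).  The limit is the last separation
of the contiguous resolved run — scanning stops at the first failure, so a
lucky noise realization at a closer separation cannot shrink the limit.
Reported problem sizes: 12 separations x 5 seeds x one 256-variable
interior-point solve per cell.

Repeatability is summarized by the mean coefficient of variation,
`cv_i = 100 * std_i / mean_i` (sample standard deviation over k repeats),
averaged over bins whose mean exceeds 25% (or 10%) of the maximum of the
mean distribution; mean cv up to about 15% is the conventional
acceptability ceiling.

## Known limitations

- The effective regularization strength at SNR <= 1000 is weaker than what
  the reference resolution table implies: the sweep resolves ratios around
  1.9–2.1 at SNR 50–100 where the reference values are 2.5–2.7, and the
  L1 term beads the fat tail of the broad stand-in into small (3–27%)
  low-T2 satellite peaks on most noise realizations at SNR 1000.  No single
  lambda convention matches both the high-SNR and low-SNR reference
  behavior; the shipped convention matches the high-SNR cells exactly and
  errs on the side of *better* resolution at low SNR.
- A noise-free sweep is limited by the ground truth itself: below a ratio
  of about 1.24 the two-Gaussian mixture is intrinsically unimodal (peak
  separation under 2 standard deviations), so "resolving" it is undefined.
- Only one-dimensional (T2) kernels are supported; dictionaries beyond the
  identity are exercised through the sign-splitting interface but no
  curated wavelet/Gaussian dictionary ships with the package.
- Proprietary binary formats of commercial ILT toolboxes are not read; I/O
  is open delimited text.
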