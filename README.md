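# sparseilt

Sparse-representation inverse Laplace transform for low-resolution NMR
(CPMG) relaxometry.

A CPMG echo train measures the multiexponential decay

$$s(t_i) = \sum_j f(T_{2,j})\, e^{-t_i/T_{2,j}} + \varepsilon_i ,$$

and the quantity of scientific interest is the distribution $f(T_2)$ of
spin–spin relaxation times — a severely ill-posed inverse Laplace transform.
Classical Tikhonov (L2) inversion stabilizes the problem at the cost of
broadening, merging adjacent peaks.  `sparseilt` instead solves the
non-negative, L1+L2-regularized convex program

$$\min_{f = Bc,\; f \ge 0}\ \tfrac12\lVert K f - s\rVert_2^2
  + \lambda_1 \lVert c\rVert_1 + \tfrac12\lambda_2 \lVert c\rVert_2^2 ,$$

with $K_{ij} = e^{-t_i/T_j}$ on a log-spaced $T_2$ grid and a pluggable
sparsifying dictionary $B$ (identity by default), using a primal-dual
interior-point method whose per-iteration cost is one positive-definite
normal-equations solve.  The regularization weights follow the SNR-scaled
universal rule

$$\lambda_1 = \alpha_1 \beta / \mathrm{SNR}, \qquad
  \lambda_2 = \alpha_2 / \mathrm{SNR}, \qquad \beta = \lVert s\rVert_\infty ,$$

with conservative universal constants $\alpha_1 = 10$, $\alpha_2 = 5$
(validated down to SNR 150).  The package also ships the machinery used to
validate such a solver: a synthetic CPMG simulator with known ground-truth
spectra, an echo-train SNR estimator, repeatability (coefficient-of-variation)
statistics, and a two-peak resolution-limit sweep.

It is intended for NMR relaxometry practitioners (food science, petrophysics,
biophysics) analysing bench-top CPMG data, and for methodologists studying
regularized Laplace inversion.

## Worked example

Simulate the standard three-peak test signal 5 (peaks at 8.73, 21.54 and
53.15 ms, adjacent ratios 2.47) at SNR 1000, then invert it:

```sh
$ sparseilt simulate --signal 5 --snr 1000 --seed 1 --out demo.csv
$ sparseilt invert demo.csv --snr 1000 --out demo_spectrum.csv
peak    8.348 ms        height 0.4157
peak    22.54 ms        height 0.2894
peak    58.17 ms        height 0.5221
```

All three peaks are recovered within one to two grid bins of the true
centers (the 256-point grid spans 0.1–10 000 ms, so one bin is a factor of
1.046 in $T_2$); a pure L2 inversion at this separation returns a single
merged hump.  The spectrum file carries `(T2_ms, amplitude)` columns.

The resolution-limit sweep brings a second peak progressively closer to a
fixed peak at 81.54 ms and reports the smallest separation the inversion
still splits:

```sh
$ sparseilt resolve --width 2 --snr 10000
...
resolution limit: T22/T21 = 1.61
```

The same library calls are available in Python:

```python
import sparseilt as si

grid = si.build_t2_grid()                       # 256 points, 0.1-10000 ms
train, truth = si.simulate_echo_train(si.narrow_signal(5, snr=1000, seed=1), grid)
spectrum = si.invert_train(train, grid, snr=1000)
print(si.find_peaks(spectrum))
```

## Layout

- `sparseilt.kernel` — time/T2 grids, the Laplace kernel, truncated SVD,
  Tikhonov filter factors
- `sparseilt.solver` — the interior-point solver, dictionary sign-splitting,
  KKT diagnostics
- `sparseilt.calibration` — the SNR-scaled λ rule and the α grid search
- `sparseilt.metrics` — SNR estimation, CV repeatability, peak detection,
  resolution limits
- `sparseilt.simulate` — ground-truth spectra and synthetic echo trains
- `sparseilt.io_cli` / `sparseilt.cli` — delimited-text I/O, logarithmic
  pruning, configuration, and the `sparseilt` command

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.
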