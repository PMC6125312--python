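# Methods

## The estimation problem

The package estimates nested expectations `E = E_Y(f(Z_Y))` with
`Z_Y = E_{X|Y}(X|Y)`, for scalar `Y` and `X` and a nonlinearity `f` given by
its Taylor expansion around a point `x0`.  Three estimators share one
problem/stream infrastructure:

* **monomial product** — for `f(x) = x^n` exactly: per realisation, one outer
  draw `y` and `n` i.i.d. conditional draws whose product is retained.  This
  rests on the conditional-independence identity
  `E_Y(Z_Y^n) = E[X_1···X_n]` with all `X_q` sharing one `y`; it is unbiased
  for every `n ≥ 0` (empty product = 1).
* **NLMC** — for general smooth `f`: the Taylor sum is randomised over a
  degree law `P_N` and each realisation retains the signed weight
  `ŵ = c_N/P_N(N) · Π_{q≤N}(x_q − x0)`.  Unbiasedness needs (i) absolute
  continuity — `P_N(n) > 0` wherever `c_n ≠ 0` — which is checked before any
  sampling and aborts on failure, and (ii) enough integrability for the
  interchange of expectation and summation; the package does not assert a
  general sufficient condition (none is imposed on `(f, x0, X)`), it instead
  exposes convergence-region metadata on kernels and variance diagnostics on
  reports.
* **plug-in** — the biased baseline `f(mean of K conditional draws)`,
  implemented for the bias and cost comparisons.

A note on a sign that is easy to lose when simplifying by hand: for the
reciprocal kernel `f = 1/(1+x)` with its matched geometric law the weight
collapses to `Π (x0 − x_q)/x0` — the `(−1)^N` carried by the coefficients
flips every factor.  Writing `Π (x_q − x0)/x0` instead is wrong for odd
degrees and shifts the estimate away from the closed form `2 ln(3/2)`; the
implementation always evaluates the generic `c_n/P_N(n)·Π(x_q − x0)` form,
which cannot drop the sign, and a property test pins the collapsed identity
on random inputs.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `x0` | Taylor expansion point | 1.0 | an upper bound of the toy's inner variable; heuristic starting point, swept for the optimum |
| `P_N` | degree law | matched, scale `x0` | cancels `|c_n|` from the weight (geometric for reciprocal, Poisson for exponential) |
| `M` | outer realisations | 1e5 (CLI) | ~0.1% relative se on the toy at `x0 = 1` |
| `K` | plug-in inner samples | `1/(3t²)` at target `t` | makes the inner mean itself meet the target: the K-mean of `U(0,y)` has relative sd `1/√(3K)` for every `y`; nearest-integer rounding gives `K = 3333` at 1% |
| `target_relsd` | precision target | 0.01 | "1%" is relative standard error `sd(ŵ)/(√M·|E|)`, the convention under which `K=3333` and `M≈140` are reproduced |
| degree cap | max sampled degree | 1e5 | exceeded ⇒ error, never truncation (truncation biases) |

Pilot protocol for `M` at a target: a single fixed-size pilot (1e4
realisations for NLMC sweeps, 1e5 for the plug-in baseline) followed by the
quadratic extrapolation `M = ceil((s/t)²)`.  No sequential stopping: the
procedure's own random-generation budget is then deterministic and
reproducible.  These pilot sizes give the sizing statistic `s` a relative
error well under the ±10% band used to judge `M_1%`.

## Cost model

Cost is the exact integer count of primitive random generations (uniform
variates), never wall-clock time.  NLMC: `1 + 1 + n` per realisation
(outer + degree + inner), so `C = M(2 + E(N))`, `E(N) = x0` for the
geometric law.  Plug-in: `C = M(1 + K)`.  Every report carries its
generation ledger and tests assert the closed forms against it as integers.
A degree draw is counted even for a degenerate law and a conditional draw is
consumed even on a zero-width support, so the accounting is uniform across
problems.

The expansion point trades variance against per-realisation cost.  On the
toy problem the weight variance has the closed form (used as the oracle)

```
Var(ŵ) = ∫₀¹ dy / (1 + x0 − x0·g(y)) − (2 ln 3/2)²,
g(y) = (y²/12 + (y/2 − x0)²) / x0²,
```

finite iff `x0 > 1/6`; below that the second moment diverges, which is the
small-`x0` cost blow-up visible in the sweep.  The sweep reports the
discrete grid minimum (default grid: 15 log-spaced points in `[0.125, 32]`),
not a continuous optimum, and reports both the heuristic `x0` (an upper
bound of the inner variable) and the empirical grid optimum without
privileging either.

## Random streams and reproducibility

One root stream (numpy PCG64) per run, from which three deterministic
substreams are spawned — outer, degree, inner — each consumed sequentially;
per realisation the logical order is outer, then degree, then inner.
Keeping the roles on separate substreams (rather than interleaving one
stream) lets realisations be generated in vectorised batches while leaving
the draw sequence, the counts and bit-for-bit reproducibility independent of
batch size.  All built-in samplers are inverse-CDF maps from uniforms
(uniform supports use the half-open `[a, b)` convention), so one uniform is
exactly one counted generation; the geometric law inverts its closed-form
CDF, Poisson uses the quantile function.

Weight products are evaluated in log space with signs tracked separately
(a zero factor yields an exact zero), so realisations with large sampled
degree stay finite even when `c_N` and `P_N(N)` individually underflow;
for the same reason the absolute-continuity check judges positivity through
`log P_N(n)`, so an underflowing-but-positive tail probability is not
mistaken for structural zero mass.

## Oracles

Every stochastic estimate in the test suite is validated against a
deterministic oracle, never against another Monte Carlo run: adaptive
quadrature of `∫ p_Y(y) f(Z_y) dy` (absolute tolerance 1e−10, orders of
magnitude below any Monte Carlo standard error involved), exact enumeration
for discrete problems, and the closed-form toy variance above.  The plug-in
variance oracle uses a second-order delta-method correction for finite `K`
(variance of the K-mean propagated through `f'` and `f''`); it is an
approximation used for consistency checks only, predicting `M_1% ≈ 138` at
`K = 3333` against ~140 observed from pilots.

## What the built-in problems do and do not exercise

The built-ins (`toy`, `expdemo`, `coin`) have uniform outer and conditional
laws, bounded supports, smooth low-curvature nonlinearities and analytic
conditional means — ideal conditions under which the 4-standard-error
oracle tests are sharp.  Passing them demonstrates unbiasedness, exact cost
accounting and the variance/cost trade-off; it does **not** demonstrate
robustness to unbounded or heavy-tailed inner variables, `y`-dependent
expansion points (supported programmatically, untested beyond constants), or
nonlinearities whose Taylor series converge only marginally on the sampled
range.  For such cases the variance diagnostics are the guard rail, not a
guarantee.

## Numerical choices and limitations

* **Matched-law table.** `matched_degree` normalises `|c_n|·scaleⁿ` in log
  space and samples by inversion of a cumulative table cut where terms fall
  80 nats below the peak; the omitted sampling tail (< 1e−35 relative) is far
  beyond what double-precision inversion can reach, while `pmf`/`log_pmf`
  use the closed form for *all* `n` so the law keeps its full mathematical
  support.  A series that has not decayed within 20,000 terms is rejected as
  non-normalizable.
* **Heavy-tail watchdog.** A report is flagged (and a warning emitted) when
  the largest 1% of `|ŵ|` carry more than 50% of the total `|ŵ|` mass.  This
  is deliberately a mass-concentration diagnostic: in the toy's
  infinite-variance regime (`x0 ≤ 1/6`) the share rises well above its
  moderate-`x0` level but the bulk of near-unit weights keeps it under the
  50% threshold at moderate sample sizes, so the flag marks only severe
  concentration; the divergence itself is caught analytically by the
  variance oracle's second-moment condition.
* **Weights are signed.** Alternating Taylor coefficients make negative
  weights legitimate; the estimator averages them as-is (no absolute-value
  tricks), and reports the negative fraction (0 on the toy whenever `x0 ≥ 1`,
  since then every factor `x0 − x_q` is positive).
* **Scalar variables only.** Vector `Y` or `X` and multi-index degree laws
  for products of several nested expectations are out of scope, as are
  branching-path solvers for nonlinear integral equations, quasi-Monte Carlo
  and parallel execution.
* **Kernel coefficients are user-supplied.** No automatic or symbolic
  differentiation: a kernel is an exact lazy coefficient stream, which keeps
  the estimator's unbiasedness independent of any numerical differentiation
  error.
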