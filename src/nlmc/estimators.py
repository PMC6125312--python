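"""The three Monte Carlo estimators for nested expectations.

Given E = E_Y(f(E_{X|Y}(X|Y))), this module implements:

``monomial_product_estimate``
    The i.i.d. product trick for a pure monomial: E_Y(E_{X|Y}(X|Y)^n) equals
    the expectation of the product X_1 ... X_n of n independent conditional
    draws sharing one y, so a single (y, x_1..x_n) tuple gives one unbiased
    weight.  n = 1 is standard Monte Carlo; n = 0 is identically 1.

``nlmc_estimate``
    The non-linear Monte Carlo (NLMC) estimator.  f is Taylor-expanded
    around x0, the sum over degrees is read as an expectation over a random
    degree N ~ P_N, and each realisation retains the signed weight

        w = c_N / P_N(N) * prod_{q=1..N} (x_q - x0),
        c_n = d^n f(x0) / n!   (empty product = 1),

    whose average over realisations is unbiased for E.  Weights are signed
    (Taylor coefficients alternate); no absolute-value tricks are applied.
    Degree sampling requires absolute continuity of P_N w.r.t. the nonzero
    coefficients, checked before any sampling.

``plugin_estimate``
    The naive biased baseline: replace the inner expectation by a K-sample
    mean and apply f directly; bias is O(1/K).

Draw accounting
---------------
One run owns a root :class:`~nlmc.problems.RandomStream` and spawns three
deterministic substreams — outer (y), degree (N), inner (x) — each consumed
sequentially.  Per realisation the logical draw order is outer, then degree,
then inner; a degree draw is consumed even when the law is degenerate, and a
conditional draw is consumed even on a zero-width support, so the recorded
generation counts are exactly M outer + M degree + sum(n) inner for NLMC and
M outer + M*K inner for the plug-in.

Weight products are evaluated in log space (exact signs tracked separately),
so realisations with large sampled degree remain finite even when c_N and
P_N(N) individually under- or overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .degrees import DegreeDistribution, check_absolute_continuity
from .kernels import TaylorKernel
from .problems import (
    Accumulator,
    DiscreteProblem,
    EstimateReport,
    GenerationCounts,
    NestedProblem,
    RandomStream,
)

__all__ = [
    "WeightRealisation",
    "HeavyTailWarning",
    "monomial_product_estimate",
    "nlmc_weight",
    "nlmc_realisation",
    "nlmc_estimate",
    "plugin_estimate",
    "discrete_estimate",
]

_DEFAULT_CHUNK = 1 << 18


class HeavyTailWarning(UserWarning):
    """The largest 1% of |weights| carry more than half the |weight| mass.

    Symptomatic of a near-divergent weight second moment (e.g. the Taylor
    expansion point x0 chosen too close to 0 for the reciprocal kernel);
    the reported standard error is then unreliable.
    """


@dataclass
class WeightRealisation:
    """One NLMC realisation: the sampled tuple and its signed weight."""

    y: float
    degree: int
    inner_draws: np.ndarray
    weight: float


def _finalize(
    acc: Accumulator, weights: np.ndarray, generations: GenerationCounts
) -> EstimateReport:
    """Assemble a report with sign/heavy-tail diagnostics from raw weights."""
    m = weights.size
    neg = float(np.count_nonzero(weights < 0)) / m if m else 0.0
    abs_w = np.abs(weights)
    total = float(abs_w.sum())
    share = 0.0
    if m and total > 0.0:
        k = max(1, math.ceil(0.01 * m))
        top = np.partition(abs_w, m - k)[m - k:]
        share = float(top.sum()) / total
    report = EstimateReport(
        estimate=acc.mean,
        standard_error=acc.standard_error,
        n_samples=acc.n,
        generations=generations,
        negative_weight_fraction=neg,
        top_mass_share=share,
    )
    if report.heavy_tailed:
        warnings.warn(
            f"largest 1% of |weights| carry {share:.1%} of the |weight| mass; "
            "variance estimate unreliable (consider a larger expansion point)",
            HeavyTailWarning,
            stacklevel=3,
        )
    return report


def monomial_product_estimate(
    problem: NestedProblem,
    n: int,
    M: int,
    stream: RandomStream,
    *,
    chunk: int = _DEFAULT_CHUNK,
) -> EstimateReport:
    """Unbiased estimate of the pure monomial E_Y(E_{X|Y}(X|Y)^n).

    Per realisation: one outer draw y, then n conditional draws sharing that
    y, retaining their product (1 when n = 0).  Generation ledger: M outer +
    n*M inner, no degree draws.
    """
    n = int(n)
    if n < 0:
        raise ValueError(f"monomial degree must be >= 0; got {n}")
    if M < 1:
        raise ValueError(f"M must be >= 1; got {M}")
    s_out, s_in = stream.child(0), stream.child(2)
    acc = Accumulator()
    weights = np.empty(M)
    done = 0
    while done < M:
        m = min(chunk, M - done)
        y = np.asarray(problem.outer_from_uniform(s_out.uniform(m)), dtype=float)
        if n == 0:
            w = np.ones(m)
        else:
            u = s_in.uniform(m * n).reshape(m, n)
            x = problem.conditional_from_uniform(y[:, None], u)
            w = np.prod(x, axis=1)
        weights[done:done + m] = w
        acc.add_values(w)
        done += m
    gens = GenerationCounts(outer=s_out.position, degree=0, inner=s_in.position)
    return _finalize(acc, weights, gens)


def nlmc_weight(
    kernel: TaylorKernel,
    degrees: DegreeDistribution,
    n: int,
    inner_draws: Sequence[float],
) -> float:
    """The signed NLMC weight c_n / P_N(n) * prod(x_q - x0) for one tuple."""
    inner_draws = np.asarray(inner_draws, dtype=float)
    n = int(n)
    if inner_draws.size != n:
        raise ValueError(f"expected {n} inner draws, got {inner_draws.size}")
    p = degrees.pmf(n)
    if p == 0.0:
        raise ValueError(
            f"P_N({n}) = 0 while its Taylor coefficient may be nonzero: "
            "absolute-continuity violation"
        )
    return kernel.coeff(n) / p * float(np.prod(inner_draws - kernel.x0))


def nlmc_realisation(
    problem: NestedProblem,
    kernel: TaylorKernel,
    degrees: DegreeDistribution,
    stream: RandomStream,
) -> WeightRealisation:
    """Run one NLMC realisation on a single stream (outer, degree, inner)."""
    y = float(problem.outer_sampler(stream))
    n = int(degrees.sample(stream))
    x = np.asarray(
        problem.conditional_from_uniform(y, stream.uniform(n)), dtype=float
    ) if n else np.empty(0)
    return WeightRealisation(y=y, degree=n, inner_draws=x, weight=nlmc_weight(kernel, degrees, n, x))


def _segment_log_products(diffs: np.ndarray, counts: np.ndarray):
    """Per-segment (log|prod|, sign) of consecutive runs of ``diffs``.

    ``counts`` gives the run lengths (may be 0, empty product = 1).  Zero
    factors yield log|prod| = -inf, i.e. a product of exactly 0.
    """
    offsets = np.zeros(counts.size, dtype=np.int64)
    np.cumsum(counts[:-1], out=offsets[1:])
    with np.errstate(divide="ignore"):
        log_abs = np.log(np.abs(diffs))
    # sentinel keeps reduceat in range when the last segment is empty
    log_abs = np.append(log_abs, 0.0)
    neg = np.append((diffs < 0.0).astype(np.int64), 0)
    log_prod = np.add.reduceat(log_abs, offsets)
    neg_count = np.add.reduceat(neg, offsets)
    empty = counts == 0
    log_prod[empty] = 0.0
    neg_count[empty] = 0
    sign = np.where(neg_count % 2 == 0, 1.0, -1.0)
    return log_prod, sign


def nlmc_estimate(
    problem: NestedProblem,
    kernel: TaylorKernel,
    degrees: DegreeDistribution,
    M: int,
    stream: RandomStream,
    *,
    chunk: int = _DEFAULT_CHUNK,
) -> EstimateReport:
    """The unbiased NLMC estimate of E_Y(f(E_{X|Y}(X|Y))) from M realisations.

    Per realisation: sample y, sample a degree n ~ P_N, sample n conditional
    draws, retain the signed weight c_n/P_N(n) * prod(x_q - x0).  Aborts up
    front if P_N is not absolutely continuous w.r.t. the kernel support
    (the estimator is provably biased in that case) and raises, rather than
    truncates, if a sampled degree exceeds the law's hard cap.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1; got {M}")
    cont = check_absolute_continuity(kernel, degrees)
    if not cont:
        raise RuntimeError(
            "degree law has zero mass at degree "
            f"{cont.offending_degree} where the Taylor coefficient is nonzero; "
            "estimator would be biased"
        )
    x0 = kernel.x0
    s_out, s_deg, s_in = stream.child(0), stream.child(1), stream.child(2)
    acc = Accumulator()
    weights = np.empty(M)
    done = 0
    while done < M:
        m = min(chunk, M - done)
        y = np.asarray(problem.outer_from_uniform(s_out.uniform(m)), dtype=float)
        n = np.asarray(degrees.sample(s_deg, m), dtype=np.int64)
        total = int(n.sum())
        u = s_in.uniform(total)
        y_rep = np.repeat(y, n)
        x = np.asarray(problem.conditional_from_uniform(y_rep, u), dtype=float)

        log_prod, sign_prod = _segment_log_products(x - x0, n)

        uniq, inv = np.unique(n, return_inverse=True)
        sgn_c = np.empty(uniq.size)
        log_ratio = np.empty(uniq.size)
        for i, nv in enumerate(uniq):
            s, la = kernel.coeff_log(int(nv))
            sgn_c[i] = s
            log_ratio[i] = la - degrees.log_pmf(int(nv)) if s != 0.0 else -math.inf
        w = sgn_c[inv] * sign_prod * np.exp(log_ratio[inv] + log_prod)

        weights[done:done + m] = w
        acc.add_values(w)
        done += m
    gens = GenerationCounts(outer=s_out.position, degree=s_deg.position, inner=s_in.position)
    return _finalize(acc, weights, gens)


def plugin_estimate(
    problem: NestedProblem,
    f_eval: Callable[[np.ndarray], np.ndarray],
    K: int,
    M: int,
    stream: RandomStream,
    *,
    max_chunk_draws: int = 8_000_000,
) -> EstimateReport:
    """The naive plug-in estimate: f applied to a K-sample inner mean.

    Per realisation: one outer draw y, K conditional draws, weight
    f(mean(x_1..x_K)).  Consistent as K -> inf but biased O(1/K) at finite K;
    generation ledger: M outer + M*K inner.
    """
    K, M = int(K), int(M)
    if K < 1:
        raise ValueError(f"plug-in inner sample size K must be >= 1; got {K}")
    if M < 1:
        raise ValueError(f"M must be >= 1; got {M}")
    s_out, s_in = stream.child(0), stream.child(2)
    chunk = max(1, max_chunk_draws // K)
    acc = Accumulator()
    weights = np.empty(M)
    done = 0
    while done < M:
        m = min(chunk, M - done)
        y = np.asarray(problem.outer_from_uniform(s_out.uniform(m)), dtype=float)
        u = s_in.uniform(m * K).reshape(m, K)
        x = problem.conditional_from_uniform(y[:, None], u)
        w = np.asarray(f_eval(x.mean(axis=1)), dtype=float)
        weights[done:done + m] = w
        acc.add_values(w)
        done += m
    gens = GenerationCounts(outer=s_out.position, degree=0, inner=s_in.position)
    return _finalize(acc, weights, gens)


def discrete_estimate(
    problem: DiscreteProblem, M: int, stream: RandomStream
) -> EstimateReport:
    """Plain weighted Monte Carlo on a finite process (one draw per weight)."""
    if M < 1:
        raise ValueError(f"M must be >= 1; got {M}")
    s_out = stream.child(0)
    r = problem.sampler(s_out, M)
    w = np.asarray(problem.weights(r), dtype=float)
    acc = Accumulator()
    acc.add_values(w)
    return _finalize(acc, w, GenerationCounts(outer=s_out.position, degree=0, inner=0))
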