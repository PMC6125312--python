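"""Probability laws over the Taylor monomial degree N.

The non-linear Monte Carlo step reads the Taylor sum of f as an expectation
over a random degree N with law P_N, sum_n P_N(n) = 1.  The choice of P_N is
an importance-sampling decision: picking P_N(n) proportional to
|c_n| * scale^n cancels the coefficient magnitudes out of the weight.  For
the reciprocal kernel with scale = x0 this yields the geometric law

    P_N(n) = x0^n / (1 + x0)^(n+1),     E(N) = x0,

and for the exponential kernel it yields Poisson(x0).

Unbiasedness requires *absolute continuity*: P_N must put positive mass on
every degree whose Taylor coefficient is nonzero, otherwise those terms are
silently dropped; :func:`check_absolute_continuity` enforces this before any
estimate.  A hard cap on sampled degrees raises rather than truncates, since
silent truncation would also bias the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .kernels import TaylorKernel
from .problems import RandomStream

__all__ = [
    "DegreeDistribution",
    "geometric_degree",
    "poisson_degree",
    "matched_degree",
    "check_absolute_continuity",
    "ContinuityCheck",
    "DEGREE_CAP",
]

#: default hard cap on a sampled degree; exceeding it is an error, never a
#: truncation (truncation would bias the estimator).
DEGREE_CAP = 100_000


@dataclass
class DegreeDistribution:
    """A law P_N over nonnegative integer degrees.

    ``from_uniform`` maps one uniform variate to one degree by inversion of
    the CDF, so degree sampling costs exactly one random generation per
    realisation.  ``max_degree`` is the top of the support (None = infinite).
    """

    name: str
    pmf: Callable[[int], float]
    log_pmf: Callable[[int], float]
    from_uniform: Callable[[np.ndarray], np.ndarray]
    mean: float
    max_degree: Optional[int] = None
    cap: int = DEGREE_CAP

    def sample(self, stream: RandomStream, size: int | None = None):
        """Draw degrees (one uniform each); error if the cap is exceeded."""
        n = self.from_uniform(stream.uniform(size))
        if np.any(np.asarray(n) > self.cap):
            raise RuntimeError(
                f"sampled degree exceeds cap {self.cap}; raising instead of "
                "truncating (truncation would bias the estimator)"
            )
        return n


def geometric_degree(x0: float) -> DegreeDistribution:
    """The importance-matched law P_N(n) = x0^n/(1+x0)^(n+1), mean x0.

    This is the geometric law with success probability 1/(1+x0); it cancels
    the reciprocal kernel's coefficient magnitudes at scale x0.  Sampling is
    exact inversion of the closed-form CDF 1 - (x0/(1+x0))^(n+1), one
    uniform per draw.
    """
    x0 = float(x0)
    if x0 <= 0.0:
        raise ValueError(
            f"geometric degree law requires x0 > 0 (degenerate at the x0 -> 0 limit); got {x0}"
        )
    log_q = math.log(x0) - math.log1p(x0)  # log(x0/(1+x0)) < 0
    log_p = -math.log1p(x0)

    def pmf(n: int) -> float:
        return math.exp(log_p + n * log_q) if n >= 0 else 0.0

    def from_uniform(u):
        u = np.asarray(u, dtype=float)
        # smallest n with 1 - q^(n+1) > u  <=>  n = floor(log(1-u)/log q)
        return np.floor(np.log1p(-u) / log_q).astype(np.int64)

    return DegreeDistribution(
        name="geometric",
        pmf=pmf,
        log_pmf=lambda n: log_p + n * log_q if n >= 0 else -math.inf,
        from_uniform=from_uniform,
        mean=x0,
    )


def poisson_degree(mean_degree: float) -> DegreeDistribution:
    """Poisson(lambda) degrees: the natural match for the exponential kernel."""
    lam = float(mean_degree)
    if lam < 0.0:
        raise ValueError(f"Poisson degree law requires mean >= 0; got {lam}")

    def pmf(n: int) -> float:
        if n < 0:
            return 0.0
        if lam == 0.0:
            return 1.0 if n == 0 else 0.0
        return math.exp(-lam + n * math.log(lam) - math.lgamma(n + 1))

    def log_pmf(n: int) -> float:
        if n < 0 or (lam == 0.0 and n > 0):
            return -math.inf
        if lam == 0.0:
            return 0.0
        return -lam + n * math.log(lam) - math.lgamma(n + 1)

    frozen = stats.poisson(lam)

    def from_uniform(u):
        u = np.asarray(u, dtype=float)
        return frozen.ppf(u).astype(np.int64)

    return DegreeDistribution(
        name="poisson",
        pmf=pmf,
        log_pmf=log_pmf,
        from_uniform=from_uniform,
        mean=lam,
        max_degree=0 if lam == 0.0 else None,
    )


def matched_degree(
    kernel: TaylorKernel, scale: float, *, tail_log_tol: float = -80.0, table_limit: int = 20_000
) -> DegreeDistribution:
    """Importance-matched law P_N(n) proportional to |c_n| * scale^n.

    Built as an explicit normalized table in log space.  The table stops once
    terms have fallen ``tail_log_tol`` nats below the running maximum (a
    relative tail below ~1e-35 for the default); if the series has not
    decayed by ``table_limit`` it is declared non-normalizable.  For the
    reciprocal kernel at scale = x0 this reproduces the geometric law
    exactly; for the exponential kernel it reproduces Poisson(x0).
    """
    if scale <= 0.0:
        raise ValueError(f"matched degree law requires scale > 0; got {scale}")
    log_s = math.log(scale)

    signs_logs: list[float] = []
    n_stop = kernel.finite_degree
    limit = n_stop + 1 if n_stop is not None else table_limit
    best = -math.inf
    for n in range(limit):
        _, la = kernel.coeff_log(n)
        lt = la + n * log_s
        signs_logs.append(lt)
        best = max(best, lt)
        if n_stop is None and n > 10 and lt < best + tail_log_tol:
            break
    else:
        if n_stop is None:
            raise ValueError(
                "matched degree series |c_n| scale^n did not decay within "
                f"{table_limit} terms; non-normalizable or scale too large"
            )

    log_terms = np.asarray(signs_logs, dtype=float)
    finite = np.isfinite(log_terms)
    if not finite.any():
        raise ValueError("all matched-degree terms are zero; kernel has no mass")
    log_z = float(logsumexp(log_terms[finite]))
    with np.errstate(divide="ignore"):
        table = np.exp(log_terms - log_z)
    table[~finite] = 0.0
    cum = np.cumsum(table)
    mean = float(np.sum(np.arange(table.size) * table))
    nonzero = np.nonzero(table)[0]
    top = int(nonzero[-1])

    # pmf/log_pmf come from the closed form |c_n| scale^n / Z for *every* n,
    # not just the sampling table, so the law keeps its full mathematical
    # support; the inversion table only omits a tail of mass < exp(tail_log_tol)
    # relative, far beyond anything double-precision sampling can reach.
    def log_pmf(n: int) -> float:
        if n < 0:
            return -math.inf
        if n < log_terms.size:
            lt = float(log_terms[n])
        elif kernel.finite_degree is not None:
            return -math.inf
        else:
            _, la = kernel.coeff_log(n)
            lt = la + n * log_s
        return lt - log_z if math.isfinite(lt) else -math.inf

    def pmf(n: int) -> float:
        return math.exp(log_pmf(n))

    def from_uniform(u):
        u = np.asarray(u, dtype=float)
        idx = np.searchsorted(cum, u, side="right")
        return np.minimum(idx, top).astype(np.int64)

    return DegreeDistribution(
        name=f"matched[{kernel.name}]",
        pmf=pmf,
        log_pmf=log_pmf,
        from_uniform=from_uniform,
        mean=mean,
        max_degree=top if kernel.finite_degree is not None else None,
    )


@dataclass
class ContinuityCheck:
    """Result of the absolute-continuity (support) diagnostic."""

    passed: bool
    offending_degree: Optional[int] = None

    def __bool__(self) -> bool:
        return self.passed


def check_absolute_continuity(
    kernel: TaylorKernel, degrees: DegreeDistribution, *, probe_degrees: int = 200
) -> ContinuityCheck:
    """Fail iff some degree with a nonzero Taylor coefficient has P_N(n) = 0.

    Returns the smallest offending degree.  A degree law whose support is a
    strict superset of the kernel's is fine; the reverse provably biases the
    estimator (those Taylor terms can never be sampled).  Mass positivity is
    judged through ``log_pmf`` so that a merely *underflowing* probability
    (finite log, e.g. a far Poisson tail) is not mistaken for structural
    zero mass.
    """
    if kernel.finite_degree is not None:
        span = kernel.finite_degree + 1
    elif degrees.max_degree is not None:
        # infinite kernel support vs finite degree support: look a bit past
        # the top of the degree law for the first dropped coefficient
        span = degrees.max_degree + 1 + probe_degrees
    else:
        span = probe_degrees
    for n in range(span):
        sign, _ = kernel.coeff_log(n)
        if sign != 0.0 and degrees.log_pmf(n) == -math.inf:
            return ContinuityCheck(False, n)
    return ContinuityCheck(True)
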