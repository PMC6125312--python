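"""Deterministic ground truth for validating the Monte Carlo estimators.

Every stochastic estimate in the test suite is checked against one of these
oracles (quadrature, exact enumeration, or a closed-form variance formula),
never against another Monte Carlo run.  Quadrature uses adaptive
``scipy.integrate.quad`` with a default absolute tolerance of 1e-10, several
orders of magnitude below any Monte Carlo standard error met in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .problems import DiscreteProblem, NestedProblem

__all__ = [
    "OracleResult",
    "quadrature_nested_expectation",
    "enumerate_discrete_expectation",
    "toy_nlmc_variance_oracle",
    "toy_plugin_variance_oracle",
    "TOY_EXACT",
]

#: exact toy value E = 2 ln(3/2) for Y~U(0,1), X|Y~U(0,Y), f = 1/(1+x)
TOY_EXACT = 2.0 * math.log(1.5)


@dataclass
class OracleResult:
    value: float
    method: str
    estimated_numerical_error: float


def quadrature_nested_expectation(
    problem: NestedProblem,
    f_eval: Callable[[float], float],
    tol: float = 1e-10,
) -> OracleResult:
    """Deterministic E_Y(f(E[X|Y])) = int p_Y(y) f(Z_y) dy by quadrature.

    Uses the problem's analytic conditional mean when supplied; otherwise
    computes Z_y itself by an inner quadrature over the conditional density.
    """
    if problem.outer_density is None:
        raise ValueError(f"problem {problem.name!r} supplies no outer density")
    a, b = problem.outer_support

    if problem.conditional_mean is not None:
        z_of_y = lambda y: float(problem.conditional_mean(y))
    elif problem.conditional_density is not None:
        def z_of_y(y: float) -> float:
            lo, hi = problem.conditional_support(y)
            if hi <= lo:
                return lo
            val, _ = quad(
                lambda x: x * float(problem.conditional_density(x, y)), lo, hi,
                epsabs=tol, epsrel=tol,
            )
            return val
    else:
        raise ValueError(
            f"problem {problem.name!r} supplies neither a conditional mean "
            "nor a conditional density"
        )

    val, err = quad(
        lambda y: float(problem.outer_density(y)) * float(f_eval(z_of_y(y))),
        a, b, epsabs=tol, epsrel=tol, limit=200,
    )
    return OracleResult(value=val, method="nested-quadrature", estimated_numerical_error=err)


def enumerate_discrete_expectation(problem: DiscreteProblem) -> float:
    """Exact sum p_i w(v_i) over the finite outcome set."""
    vals = np.asarray(problem.outcomes, dtype=float)
    probs = np.asarray(problem.probabilities, dtype=float)
    return float(np.sum(probs * np.asarray(problem.weights(vals), dtype=float)))


def _toy_g(y: float, x0: float) -> float:
    """g(y) = E[((x0 - X)/x0)^2 | y] for X ~ U(0, y)."""
    return (y * y / 12.0 + (0.5 * y - x0) ** 2) / (x0 * x0)


def toy_nlmc_variance_oracle(x0: float) -> tuple[float, int]:
    """Closed-form weight variance of the toy NLMC estimator at x0.

    Conditioned on y, the weight w = prod((x0 - X_q)/x0) over a geometric
    degree N has second moment sum_n P_N(n) g(y)^n = 1/(1 + x0 - x0 g(y))
    with g(y) = (y^2/12 + (y/2 - x0)^2)/x0^2, provided x0 g(y) < 1 + x0 for
    all y in [0, 1] (equivalent to x0 > 1/6; below that the variance is
    infinite — the small-x0 cost blow-up).  Returns (Var(w), predicted
    number of realisations for 1% relative standard deviation).
    """
    x0 = float(x0)
    if x0 <= 0.0:
        raise ValueError(f"x0 must be > 0; got {x0}")
    g_max = max(_toy_g(0.0, x0), _toy_g(1.0, x0))  # g is convex quadratic in y
    if x0 * g_max >= 1.0 + x0:
        raise ValueError(
            f"weight second moment diverges at x0={x0}: "
            f"sup_y x0*g(y) = {x0 * g_max:.6g} >= 1 + x0 = {1 + x0:.6g}"
        )
    second, _ = quad(lambda y: 1.0 / (1.0 + x0 - x0 * _toy_g(y, x0)), 0.0, 1.0,
                     epsabs=1e-12, epsrel=1e-12)
    var = second - TOY_EXACT**2
    m_predicted = math.ceil(var / (0.01 * TOY_EXACT) ** 2)
    return var, int(m_predicted)


def toy_plugin_variance_oracle(K: Optional[int] = None) -> tuple[float, int]:
    """Delta-method weight variance of the toy plug-in estimator at inner
    sample size K (K = None gives the exact K -> infinity limit).

    The K-sample inner mean S_K of U(0, y) draws has mean m = y/2 and
    variance s2 = y^2/(12 K); expanding f = 1/(1+x) to second order around m,

        E[w   | y] ~ f(m) + f''(m) s2 / 2,
        E[w^2 | y] ~ f(m)^2 + (f'(m)^2 + f(m) f''(m)) s2,

    and the outer averages are taken by quadrature.  The limiting variance is
    int_0^1 dy/(1+y/2)^2 - (2 ln 3/2)^2 = 2/3 - (2 ln 3/2)^2 ~ 0.00906.
    Returns (Var(w), predicted realisations for 1% relative sd).  The
    finite-K correction is an approximation used for consistency checks, not
    ground truth.
    """
    f = lambda x: 1.0 / (1.0 + x)
    fp = lambda x: -1.0 / (1.0 + x) ** 2
    fpp = lambda x: 2.0 / (1.0 + x) ** 3
    if K is None:
        s2 = lambda y: 0.0
    else:
        if K < 1:
            raise ValueError(f"K must be >= 1; got {K}")
        s2 = lambda y: y * y / (12.0 * K)
    mean, _ = quad(lambda y: f(0.5 * y) + 0.5 * fpp(0.5 * y) * s2(y), 0.0, 1.0,
                   epsabs=1e-12, epsrel=1e-12)
    second, _ = quad(
        lambda y: f(0.5 * y) ** 2 + (fp(0.5 * y) ** 2 + f(0.5 * y) * fpp(0.5 * y)) * s2(y),
        0.0, 1.0, epsabs=1e-12, epsrel=1e-12,
    )
    var = second - mean * mean
    m_predicted = math.ceil(var / (0.01 * mean) ** 2)
    return var, int(m_predicted)
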