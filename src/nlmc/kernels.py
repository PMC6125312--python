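"""Taylor kernels: the nonlinearity f as a lazy coefficient stream.

The estimator never evaluates f directly.  It only ever needs the Taylor
coefficients around the expansion point x0,

    c_n = d^n f(x0) / n!,        f(x) = sum_n c_n (x - x0)^n,

so a kernel is a *stream* n -> c_n, never a truncated array: truncation would
bias the estimator, so it exists only inside the :func:`validate_kernel`
diagnostic.  ``f_eval`` is carried along purely for deterministic oracles.

Built-ins: the reciprocal kernel f(x) = 1/(1+x) (light-limited growth-rate
shape of a photobioreactor at unit parameters), the exponential kernel
f(x) = exp(-x) (Beer-law attenuation), and arbitrary polynomials.

Kernels also expose ``coeff_log(n) -> (sign, log|c_n|)``.  The built-ins
override it with exact closed forms so weight evaluation stays finite even
when c_n itself under- or overflows in double precision at large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TaylorKernel",
    "reciprocal_kernel",
    "exponential_kernel",
    "polynomial_kernel",
    "validate_kernel",
]


@dataclass
class TaylorKernel:
    """The nonlinearity f represented by (x0, coefficient stream).

    Fields
    ------
    x0 : expansion point.
    coeff : n -> c_n = d^n f(x0)/n!.
    f_eval : direct evaluation of f (oracles only; never used by estimators).
    in_convergence_region : x -> bool, where the Taylor series converges.
    finite_degree : highest nonzero degree for polynomials, else None.
    coeff_log : n -> (sign, log|c_n|) with sign in {-1, 0, +1}; defaults to
        taking logs of ``coeff`` but built-ins supply exact closed forms.
    """

    name: str
    x0: float
    coeff: Callable[[int], float]
    f_eval: Callable[[np.ndarray], np.ndarray]
    in_convergence_region: Callable[[float], bool]
    finite_degree: Optional[int] = None
    coeff_log: Optional[Callable[[int], tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.coeff_log is None:
            def _default_log(n: int, _c=self.coeff) -> tuple[float, float]:
                c = _c(n)
                if c == 0.0:
                    return 0.0, -math.inf
                return math.copysign(1.0, c), math.log(abs(c))
            self.coeff_log = _default_log


def reciprocal_kernel(x0: float) -> TaylorKernel:
    """f(x) = 1/(1+x) expanded around x0 > -1.

    c_n = (-1)^n / (1+x0)^(n+1); the series converges for |x-x0| < 1+x0
    (distance to the pole at x = -1).
    """
    x0 = float(x0)
    if x0 <= -1.0:
        raise ValueError(f"reciprocal kernel requires x0 > -1 (pole at -1); got {x0}")
    log1p_x0 = math.log1p(x0)

    def coeff(n: int) -> float:
        return (-1.0) ** n / (1.0 + x0) ** (n + 1)

    def coeff_log(n: int) -> tuple[float, float]:
        return (1.0 if n % 2 == 0 else -1.0), -(n + 1) * log1p_x0

    return TaylorKernel(
        name="reciprocal",
        x0=x0,
        coeff=coeff,
        f_eval=lambda x: 1.0 / (1.0 + np.asarray(x, dtype=float)),
        in_convergence_region=lambda x: abs(x - x0) < 1.0 + x0,
        coeff_log=coeff_log,
    )


def exponential_kernel(x0: float) -> TaylorKernel:
    """f(x) = exp(-x) expanded around x0; c_n = (-1)^n exp(-x0)/n!, entire."""
    x0 = float(x0)

    def coeff(n: int) -> float:
        return (-1.0) ** n * math.exp(-x0) / math.factorial(n)

    def coeff_log(n: int) -> tuple[float, float]:
        return (1.0 if n % 2 == 0 else -1.0), -x0 - math.lgamma(n + 1)

    return TaylorKernel(
        name="exponential",
        x0=x0,
        coeff=coeff,
        f_eval=lambda x: np.exp(-np.asarray(x, dtype=float)),
        in_convergence_region=lambda x: True,
        coeff_log=coeff_log,
    )


def polynomial_kernel(coeffs_in_x: list[float], x0: float = 0.0) -> TaylorKernel:
    """A polynomial sum_k a_k x^k re-expanded around x0.

    The shifted coefficients follow from the binomial theorem:
    c_n = sum_{k >= n} a_k C(k, n) x0^(k-n); they vanish beyond the degree,
    and f_eval is the exact polynomial, so validate_kernel reports error 0
    once n_max reaches the degree.
    """
    a = np.asarray(coeffs_in_x, dtype=float)
    if a.size == 0:
        a = np.zeros(1)
    x0 = float(x0)
    deg = int(a.size - 1)
    shifted = np.zeros(deg + 1)
    for n in range(deg + 1):
        shifted[n] = sum(
            a[k] * math.comb(k, n) * x0 ** (k - n) for k in range(n, deg + 1)
        )

    def coeff(n: int) -> float:
        return float(shifted[n]) if 0 <= n <= deg else 0.0

    return TaylorKernel(
        name="polynomial",
        x0=x0,
        coeff=coeff,
        f_eval=lambda x: np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), a),
        in_convergence_region=lambda x: True,
        finite_degree=deg,
    )


def validate_kernel(
    kernel: TaylorKernel, test_points: list[float], n_max: int
) -> float:
    """Max |f(x) - truncated Taylor sum| over in-region test points.

    Points outside the kernel's convergence region are excluded from the
    maximum (the partial sums diverge there by construction, which says
    nothing about the coefficients).  Diagnostic only: the estimators never
    truncate.
    """
    worst = 0.0
    for x in test_points:
        if not kernel.in_convergence_region(x):
            continue
        dx = x - kernel.x0
        partial = 0.0
        term = 1.0  # dx^n, built incrementally
        for n in range(n_max + 1):
            partial += kernel.coeff(n) * term
            term *= dx
        worst = max(worst, abs(float(kernel.f_eval(x)) - partial))
    return worst
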