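"""Computational cost model and precision-targeted sample sizing.

Cost is defined as the total number of primitive random generations needed
to reach a precision target, never wall-clock time.  Each NLMC realisation
consumes 1 outer + 1 degree + N inner generations, so

    C_nlmc   = M * (2 + E(N))        (= M * (2 + x0) for the geometric law),
    C_plugin = M * (1 + K).

"1% standard deviation" is interpreted throughout as *relative* standard
error, s = sd(w)/|E(w)|: the number of realisations for target t is then
M_t = ceil((s/t)^2).  The expansion point x0 controls a trade-off: small x0
means cheap realisations (E(N) = x0 small) but large weight variance
(diverging as x0 -> 0), large x0 means tame variance but expensive
realisations; :func:`sweep_x0` maps the trade-off and
:func:`compare_naive_vs_nlmc` pits its minimum against the plug-in baseline.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .degrees import matched_degree
from .estimators import HeavyTailWarning, nlmc_estimate, plugin_estimate
from .kernels import TaylorKernel
from .problems import EstimateReport, NestedProblem, RandomStream

__all__ = [
    "cost_nlmc",
    "cost_plugin",
    "required_inner_samples_toy",
    "required_outer_samples",
    "sweep_x0",
    "compare_naive_vs_nlmc",
    "DEFAULT_X0_GRID",
    "COST_COLUMNS",
]

#: default expansion-point sweep: 15 log-spaced points spanning [0.125, 32]
DEFAULT_X0_GRID: np.ndarray = np.geomspace(0.125, 32.0, 15)

#: CostTable schema (one row per swept x0)
COST_COLUMNS = ["x0", "M_target", "mean_degree", "cost", "flagged"]


def cost_nlmc(M: int, mean_degree: float) -> float:
    """Total random generations M*(2 + E(N)) of an NLMC run."""
    if M < 0 or mean_degree < 0:
        raise ValueError("M and mean_degree must be nonnegative")
    return M * (2.0 + mean_degree)


def cost_plugin(M: int, K: int) -> int:
    """Total random generations M*(1 + K) of a plug-in run."""
    if M < 0 or K < 0:
        raise ValueError("M and K must be nonnegative")
    return int(M) * (1 + int(K))


def required_inner_samples_toy(target_relsd: float) -> int:
    """Inner sample size K giving the target relative sd of the inner mean
    for a Uniform(0, y) conditional law.

    The K-mean of U(0, y) draws has sd (y/sqrt(12))/sqrt(K) and mean y/2, so
    its relative sd is 1/sqrt(3K) independently of y; solving
    1/sqrt(3K) = t gives K = 1/(3 t^2), rounded to the nearest integer
    (K_1% = 3333 at t = 0.01).
    """
    t = float(target_relsd)
    if not 0.0 < t < 1.0:
        raise ValueError(f"target relative sd must lie in (0, 1); got {t}")
    return int(round(1.0 / (3.0 * t * t)))


def required_outer_samples(
    run_pilot: Callable[[int, RandomStream], EstimateReport],
    target_relsd: float,
    pilot_M: int,
    stream: RandomStream,
) -> int:
    """Realisations needed for a target relative sd, sized from one pilot.

    Runs ``run_pilot(pilot_M, stream)``, reads the per-realisation relative
    standard deviation s = sd(w)/|mean(w)| off the report, and extrapolates
    quadratically: M = ceil((s / target)^2), at least 1.  A single fixed-size
    pilot (no sequential stopping) keeps the procedure's own random-
    generation budget deterministic.
    """
    if pilot_M < 1000:
        raise ValueError(f"pilot_M must be >= 1000 for a stable variance; got {pilot_M}")
    report = run_pilot(pilot_M, stream)
    if not math.isfinite(report.estimate) or report.estimate == 0.0:
        raise RuntimeError(
            f"pilot estimate {report.estimate!r} is zero or non-finite; "
            "cannot size for a relative precision target"
        )
    s = report.relative_sd
    return max(1, math.ceil((s / float(target_relsd)) ** 2))


def sweep_x0(
    problem: NestedProblem,
    kernel_family: Callable[[float], TaylorKernel],
    grid: Sequence[float],
    target_relsd: float,
    stream: RandomStream,
    *,
    pilot_M: int = 10_000,
) -> pd.DataFrame:
    """Map the x0 trade-off: per grid point, the realisations M_target needed
    for the precision target (via a pilot) and the cost M_target*(2 + E(N)).

    The degree law at each x0 is the importance-matched law at scale x0
    (the geometric law for the reciprocal kernel).  Rows whose pilot trips
    the heavy-tail watchdog — the near-divergent-variance regime at small
    x0 — are flagged, not fatal.  Returns a table with columns
    (x0, M_target, mean_degree, cost, flagged).
    """
    rows = []
    for i, x0 in enumerate(grid):
        kernel = kernel_family(float(x0))
        deg = matched_degree(kernel, float(x0))
        sub = stream.child(20 + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HeavyTailWarning)
            pilot = lambda M, s: nlmc_estimate(problem, kernel, deg, M, s)
            report = pilot(pilot_M, sub)
            s = report.relative_sd
        m_target = max(1, math.ceil((s / float(target_relsd)) ** 2))
        rows.append(
            {
                "x0": float(x0),
                "M_target": int(m_target),
                "mean_degree": float(deg.mean),
                "cost": int(round(cost_nlmc(m_target, deg.mean))),
                "flagged": bool(report.heavy_tailed),
            }
        )
    return pd.DataFrame(rows, columns=COST_COLUMNS)


def compare_naive_vs_nlmc(
    problem: NestedProblem,
    kernel_family: Callable[[float], TaylorKernel],
    grid: Sequence[float],
    target_relsd: float,
    stream: RandomStream,
    *,
    pilot_M_plugin: int = 100_000,
    pilot_M_nlmc: int = 10_000,
) -> dict:
    """Cost of the naive plug-in vs the best NLMC point on the x0 grid.

    The plug-in inner size K is fixed analytically so the inner mean itself
    meets the precision target (valid for the uniform-conditional built-in
    problems); its outer count comes from a plug-in pilot.  The NLMC cost is
    the minimum of the sweep table — the discrete grid optimum, not a
    continuous one.  Returns the two costs, their fold-ratio, and both point
    estimates with standard errors.
    """
    kernel_probe = kernel_family(float(grid[0]))
    f_eval = kernel_probe.f_eval

    K = required_inner_samples_toy(target_relsd)
    plugin_stream = stream.child(10)
    pilot_report = plugin_estimate(problem, f_eval, K, pilot_M_plugin, plugin_stream)
    s = pilot_report.relative_sd
    naive_M = max(1, math.ceil((s / float(target_relsd)) ** 2))
    naive_cost = cost_plugin(naive_M, K)

    table = sweep_x0(problem, kernel_family, grid, target_relsd, stream, pilot_M=pilot_M_nlmc)
    best = table.loc[table["cost"].idxmin()]
    nlmc_cost = int(best["cost"])

    best_kernel = kernel_family(float(best["x0"]))
    best_deg = matched_degree(best_kernel, float(best["x0"]))
    nlmc_report = nlmc_estimate(
        problem, best_kernel, best_deg, int(best["M_target"]), stream.child(11)
    )

    return {
        "target_relsd": float(target_relsd),
        "naive_K": int(K),
        "naive_M": int(naive_M),
        "naive_cost": int(naive_cost),
        "naive_estimate": pilot_report.estimate,
        "naive_stderr": pilot_report.standard_error,
        "nlmc_best_x0": float(best["x0"]),
        "nlmc_M": int(best["M_target"]),
        "nlmc_min_cost": nlmc_cost,
        "nlmc_estimate": nlmc_report.estimate,
        "nlmc_stderr": nlmc_report.standard_error,
        "cost_ratio": naive_cost / nlmc_cost,
        "sweep": table,
    }
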