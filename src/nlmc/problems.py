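"""Nested-expectation problem definitions and Monte Carlo plumbing.

A *nested expectation* is a quantity of the form

    E = E_Y( f( E_{X|Y}(X | Y) ) ),

an outer average over a random variable ``Y`` of a (possibly nonlinear)
function ``f`` of the inner conditional mean ``Z_y = E[X | Y = y]``.  This
module supplies the ingredients every estimator in the package consumes:

* :class:`RandomStream` — a counted, spawnable uniform random stream, so that
  every primitive random generation is accounted for exactly (the cost model
  is defined purely in terms of such counts);
* :class:`NestedProblem` — samplers, supports and (optionally) densities and
  the analytic conditional mean for a continuous nested problem;
* :class:`DiscreteProblem` — a finite weighted process, the "weighted coin"
  worked example of plain Monte Carlo;
* :class:`Accumulator` — mergeable running moments (Welford/Chan);
* :class:`EstimateReport` — an estimate with its standard error and the exact
  ledger of random generations that produced it.

Built-in problems
-----------------
``make_toy_problem``
    Y ~ Uniform(0, 1), X|Y ~ Uniform(0, Y); paired with the reciprocal
    nonlinearity f(x) = 1/(1+x) this has the closed form E = 2 ln(3/2).
``make_coin_problem``
    The fair coin with weights w(0) = 2, w(1) = 8, so that E = 5.
``make_expdemo_problem``
    Y ~ Uniform(0, 2), X|Y ~ Uniform(0, Y); paired with the exponential
    nonlinearity f(x) = exp(-x) (Beer-law attenuation of a ray through a
    medium of random optical thickness) this has E = 1 - exp(-1).

Uniform sampling uses the half-open convention [a, b) throughout; this is
irrelevant to every expectation but pinned down for bit-for-bit determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "RandomStream",
    "NestedProblem",
    "DiscreteProblem",
    "Accumulator",
    "GenerationCounts",
    "EstimateReport",
    "make_toy_problem",
    "make_coin_problem",
    "make_expdemo_problem",
    "running_moments",
    "get_problem",
]


class RandomStream:
    """A seeded uniform random stream with an exact draw counter.

    Wraps ``numpy.random.Generator(PCG64)``.  Identical ``(seed, spawn_key)``
    pairs reproduce the draw sequence bit-for-bit; children spawned with
    :meth:`child` are statistically independent and fully determined by the
    parent seed and the child index.  ``position`` counts every uniform
    variate ever drawn from this stream, which is what the computational-cost
    model counts.
    """

    def __init__(self, seed: int, spawn_key: tuple[int, ...] = ()):
        self.seed = int(seed)
        self.spawn_key = tuple(int(k) for k in spawn_key)
        self._gen = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=self.spawn_key))
        )
        self.position = 0

    def uniform(self, size: int | None = None):
        """Draw ``size`` uniforms on [0, 1) (a scalar when ``size is None``)."""
        self.position += 1 if size is None else int(size)
        return self._gen.random(size)

    def child(self, index: int) -> "RandomStream":
        """Deterministic independent substream number ``index``."""
        return RandomStream(self.seed, self.spawn_key + (int(index),))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RandomStream(seed={self.seed}, spawn_key={self.spawn_key}, position={self.position})"


@dataclass
class NestedProblem:
    """A scalar nested-expectation problem Y -> X|Y.

    Samplers are expressed as inverse-CDF maps from uniforms so that one
    uniform variate corresponds to exactly one random generation; both maps
    must accept numpy arrays elementwise.

    Parameters
    ----------
    outer_from_uniform
        u -> y, the inverse CDF of Y.
    conditional_from_uniform
        (y, u) -> x, the inverse conditional CDF of X|Y=y.  A zero-width
        (degenerate) support must map every u to the support point; the
        uniform is consumed regardless so that generation accounting stays
        uniform across realisations.
    outer_support, conditional_support
        Closed intervals [a, b]; ``conditional_support`` is a function of y.
    conditional_mean, outer_density, conditional_density
        Optional analytic pieces used by the deterministic oracles.
    """

    name: str
    outer_from_uniform: Callable[[np.ndarray], np.ndarray]
    conditional_from_uniform: Callable[[np.ndarray, np.ndarray], np.ndarray]
    outer_support: tuple[float, float]
    conditional_support: Callable[[float], tuple[float, float]]
    conditional_mean: Optional[Callable[[np.ndarray], np.ndarray]] = None
    outer_density: Optional[Callable[[np.ndarray], np.ndarray]] = None
    conditional_density: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None

    def outer_sampler(self, stream: RandomStream, size: int | None = None):
        """Draw y from Y (one random generation per value)."""
        return self.outer_from_uniform(stream.uniform(size))

    def conditional_sampler(self, y, stream: RandomStream, size: int | None = None):
        """Draw x from X|Y=y (one random generation per value)."""
        return self.conditional_from_uniform(y, stream.uniform(size))


@dataclass
class DiscreteProblem:
    """A finite weighted process E = sum_i p_i w(v_i)."""

    name: str
    outcomes: Sequence[float]
    probabilities: Sequence[float]
    weights: Callable[[float], float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        self._cum = np.cumsum(p)

    def sampler(self, stream: RandomStream, size: int | None = None):
        """Draw outcomes by inversion (one uniform per outcome)."""
        u = stream.uniform(size)
        idx = np.searchsorted(self._cum, u, side="right")
        idx = np.minimum(idx, len(self.outcomes) - 1)
        return np.asarray(self.outcomes, dtype=float)[idx]


class Accumulator:
    """Running count/mean/centered-second-moment, mergeable.

    Uses Welford updates for scalars and Chan's parallel formula for merges,
    so merging two accumulators is numerically equivalent (to ~1e-12
    relative) to accumulating the concatenated sequence.
    """

    __slots__ = ("n", "mean", "m2")

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0

    def add(self, x: float) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def add_values(self, values: np.ndarray) -> None:
        """Accumulate a whole batch (two-pass on the batch, then merge)."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return
        other = Accumulator()
        other.n = int(values.size)
        other.mean = float(values.mean())
        other.m2 = float(((values - other.mean) ** 2).sum())
        self.merge(other)

    def merge(self, other: "Accumulator") -> "Accumulator":
        if other.n == 0:
            return self
        if self.n == 0:
            self.n, self.mean, self.m2 = other.n, other.mean, other.m2
            return self
        n = self.n + other.n
        delta = other.mean - self.mean
        self.mean += delta * other.n / n
        self.m2 += other.m2 + delta * delta * self.n * other.n / n
        self.n = n
        return self

    @property
    def variance(self) -> float:
        """Sample variance (ddof=1); 0 for fewer than two values."""
        return self.m2 / (self.n - 1) if self.n > 1 else 0.0

    @property
    def standard_error(self) -> float:
        return math.sqrt(self.variance / self.n) if self.n else float("nan")


def running_moments(values: Sequence[float]) -> Accumulator:
    """One-pass running moments of a nonempty sequence."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("running_moments requires at least one value")
    acc = Accumulator()
    for v in values.ravel():
        acc.add(float(v))
    return acc


@dataclass
class GenerationCounts:
    """Exact counts of primitive random generations by role."""

    outer: int = 0
    degree: int = 0
    inner: int = 0

    @property
    def total(self) -> int:
        return self.outer + self.degree + self.inner

    def to_dict(self) -> dict:
        return {"outer": self.outer, "degree": self.degree, "inner": self.inner}


@dataclass
class EstimateReport:
    """A Monte Carlo estimate with its exact generation ledger.

    ``cost`` is the total number of primitive random generations, the
    currency of the computational-cost model.  ``negative_weight_fraction``
    and ``top_mass_share`` (share of total |w| mass carried by the largest 1%
    of |w|) are variance diagnostics; ``heavy_tailed`` flags
    top_mass_share > 0.5, the watchdog for the small-x0 variance blow-up.
    """

    estimate: float
    standard_error: float
    n_samples: int
    generations: GenerationCounts = field(default_factory=GenerationCounts)
    negative_weight_fraction: float = 0.0
    top_mass_share: float = 0.0

    @property
    def cost(self) -> int:
        return self.generations.total

    @property
    def heavy_tailed(self) -> bool:
        return self.top_mass_share > 0.5

    @property
    def relative_sd(self) -> float:
        """Per-realisation relative standard deviation s = sd(w)/|mean(w)|."""
        return self.standard_error * math.sqrt(self.n_samples) / abs(self.estimate)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "stderr": self.standard_error,
            "n": self.n_samples,
            "generations": self.generations.to_dict(),
            "cost": self.cost,
            "negative_weight_fraction": self.negative_weight_fraction,
            "top_mass_share": self.top_mass_share,
            "heavy_tailed": self.heavy_tailed,
        }


# ---------------------------------------------------------------------------
# Built-in problems
# ---------------------------------------------------------------------------

def make_toy_problem() -> NestedProblem:
    """Y ~ U(0,1), X|Y ~ U(0,Y).

    With f(x) = 1/(1+x) the nested expectation is
    ``E = \\int_0^1 dy / (1 + y/2) = 2 ln(3/2)``.  The conditional density is
    1/y on [0, y]; at y = 0 the conditional law degenerates to the point 0
    (the sampler still consumes its uniform).
    """

    def cond_density(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.where((x >= 0) & (x <= y) & (y > 0), 1.0 / np.where(y > 0, y, 1.0), 0.0)

    return NestedProblem(
        name="toy",
        outer_from_uniform=lambda u: u,
        conditional_from_uniform=lambda y, u: y * u,
        outer_support=(0.0, 1.0),
        conditional_support=lambda y: (0.0, y),
        conditional_mean=lambda y: 0.5 * np.asarray(y, dtype=float),
        outer_density=lambda y: np.where(
            (np.asarray(y, float) >= 0) & (np.asarray(y, float) <= 1), 1.0, 0.0
        ),
        conditional_density=cond_density,
    )


def make_expdemo_problem() -> NestedProblem:
    """Y ~ U(0,2), X|Y ~ U(0,Y): exponential-attenuation demo.

    Y plays the role of a random optical thickness scale; with the Beer-law
    nonlinearity f(x) = exp(-x) applied to the conditional mean Z_y = y/2 the
    target is ``E = (1/2)\\int_0^2 exp(-y/2) dy = 1 - exp(-1)``.
    """

    def cond_density(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.where((x >= 0) & (x <= y) & (y > 0), 1.0 / np.where(y > 0, y, 1.0), 0.0)

    return NestedProblem(
        name="expdemo",
        outer_from_uniform=lambda u: 2.0 * u,
        conditional_from_uniform=lambda y, u: y * u,
        outer_support=(0.0, 2.0),
        conditional_support=lambda y: (0.0, y),
        conditional_mean=lambda y: 0.5 * np.asarray(y, dtype=float),
        outer_density=lambda y: np.where(
            (np.asarray(y, float) >= 0) & (np.asarray(y, float) <= 2), 0.5, 0.0
        ),
        conditional_density=cond_density,
    )


def make_coin_problem() -> DiscreteProblem:
    """Fair coin, weights w(0)=2 and w(1)=8, so E = 5 exactly."""
    return DiscreteProblem(
        name="coin",
        outcomes=[0.0, 1.0],
        probabilities=[0.5, 0.5],
        weights=lambda r: np.where(np.asarray(r, dtype=float) == 0.0, 2.0, 8.0),
    )


_BUILTINS = {
    "toy": make_toy_problem,
    "expdemo": make_expdemo_problem,
    "coin": make_coin_problem,
}


def get_problem(name: str):
    """Look up a built-in problem by config name ('toy', 'expdemo', 'coin')."""
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise KeyError(
            f"unknown problem {name!r}; built-ins are {sorted(_BUILTINS)}"
        ) from None
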