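"""Estimator correctness: unbiasedness vs oracles, weights, draw accounting."""

import math

import numpy as np
import pytest

import nlmc


def _z(report, target):
    return abs(report.estimate - target) / report.standard_error


class TestMonomialProduct:
    def test_first_moment(self, toy, stream):
        rep = nlmc.monomial_product_estimate(toy, 1, 300_000, stream)
        assert _z(rep, 0.25) < 4  # E_Y(Y/2)

    def test_second_moment(self, toy, stream):
        rep = nlmc.monomial_product_estimate(toy, 2, 300_000, stream)
        assert _z(rep, 1.0 / 12.0) < 4  # E_Y((Y/2)^2)

    def test_degree_zero_is_exactly_one(self, toy, stream):
        rep = nlmc.monomial_product_estimate(toy, 0, 1000, stream)
        assert rep.estimate == 1.0 and rep.standard_error == 0.0

    def test_negative_degree_rejected(self, toy, stream):
        with pytest.raises(ValueError, match=">= 0"):
            nlmc.monomial_product_estimate(toy, -1, 100, stream)

    def test_generation_accounting(self, toy, stream):
        rep = nlmc.monomial_product_estimate(toy, 3, 5000, stream)
        assert rep.generations.outer == 5000
        assert rep.generations.degree == 0
        assert rep.generations.inner == 3 * 5000
        assert rep.cost == 5000 * 4


class TestNlmcWeight:
    def test_empty_product_weight(self):
        k, g = nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0)
        assert nlmc.nlmc_weight(k, g, 0, []) == pytest.approx(1.0)  # (1/2)/(1/2)

    def test_even_degree_example(self):
        k, g = nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0)
        assert nlmc.nlmc_weight(k, g, 2, [0.2, 0.5]) == pytest.approx(0.8 * 0.5)

    def test_linear_kernel_returns_draw(self):
        k = nlmc.polynomial_kernel([0.0, 1.0], 0.0)
        deg = nlmc.matched_degree(k, 1.0)  # all mass on degree 1
        assert deg.pmf(1) == pytest.approx(1.0)
        assert nlmc.nlmc_weight(k, deg, 1, [0.7]) == pytest.approx(0.7)

    def test_zero_mass_degree_rejected(self):
        k = nlmc.reciprocal_kernel(1.0)
        deg = nlmc.matched_degree(nlmc.polynomial_kernel([0, 0, 1], 1.0), 1.0)
        with pytest.raises(ValueError, match="continuity"):
            nlmc.nlmc_weight(k, deg, 5, [0.1] * 5)

    def test_wrong_draw_count_rejected(self):
        k, g = nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0)
        with pytest.raises(ValueError, match="inner draws"):
            nlmc.nlmc_weight(k, g, 3, [0.1, 0.2])

    def test_sign_corrected_closed_form(self):
        """For the reciprocal kernel with its matched geometric law the weight
        collapses to prod((x0 - x_q)/x0): the (-1)^n of the coefficients
        flips every factor.  Checked on 1000 random (x0, n, draws)."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            x0 = float(rng.uniform(0.05, 10.0))
            n = int(rng.integers(0, 21))
            xs = rng.random(n)
            w = nlmc.nlmc_weight(
                nlmc.reciprocal_kernel(x0), nlmc.geometric_degree(x0), n, xs
            )
            ref = float(np.prod((x0 - xs) / x0))
            worst = max(worst, abs(w - ref) / max(abs(ref), 1e-300))
        assert worst < 1e-12


class TestNlmcEstimate:
    def test_toy_reciprocal_geometric(self, toy, stream):
        rep = nlmc.nlmc_estimate(
            toy, nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0), 300_000, stream
        )
        assert _z(rep, nlmc.TOY_EXACT) < 4

    def test_linear_kernel_identical_to_standard_mc(self, toy):
        """With f(x) = x and all degree mass on 1, NLMC *is* standard MC:
        same draws, same weights, realisation by realisation."""
        k = nlmc.polynomial_kernel([0.0, 1.0], 0.0)
        deg = nlmc.matched_degree(k, 1.0)
        a = nlmc.nlmc_estimate(toy, k, deg, 50_000, nlmc.RandomStream(9))
        b = nlmc.monomial_product_estimate(toy, 1, 50_000, nlmc.RandomStream(9))
        assert a.estimate == b.estimate
        assert a.standard_error == b.standard_error

    def test_degenerate_outer_exponential(self, stream):
        """Y fixed at 1, X|Y ~ U(0,1): E = exp(-E[X]) = exp(-1/2)."""
        problem = nlmc.NestedProblem(
            name="degenerate",
            outer_from_uniform=lambda u: np.ones_like(np.asarray(u, float)),
            conditional_from_uniform=lambda y, u: np.asarray(u, float),
            outer_support=(1.0, 1.0),
            conditional_support=lambda y: (0.0, 1.0),
            conditional_mean=lambda y: 0.5 * np.ones_like(np.asarray(y, float)),
        )
        rep = nlmc.nlmc_estimate(
            problem, nlmc.exponential_kernel(1.0), nlmc.poisson_degree(1.0),
            400_000, stream,
        )
        assert _z(rep, math.exp(-0.5)) < 4

    def test_generation_accounting_exact(self, toy, stream):
        rep = nlmc.nlmc_estimate(
            toy, nlmc.reciprocal_kernel(2.0), nlmc.geometric_degree(2.0), 20_000, stream
        )
        assert rep.generations.outer == 20_000
        assert rep.generations.degree == 20_000
        assert rep.cost == 2 * 20_000 + rep.generations.inner

    def test_continuity_violation_aborts(self, toy, stream):
        finite = nlmc.matched_degree(nlmc.polynomial_kernel([0, 0, 1], 1.0), 1.0)
        with pytest.raises(RuntimeError, match="zero mass at degree 3"):
            nlmc.nlmc_estimate(toy, nlmc.reciprocal_kernel(1.0), finite, 100, stream)

    def test_no_negative_weights_when_x0_bounds_draws(self, toy, stream):
        """x0 >= 1 dominates every toy inner draw, so every factor x0 - x_q
        is positive and no weight is negative."""
        rep = nlmc.nlmc_estimate(
            toy, nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0), 50_000, stream
        )
        assert rep.negative_weight_fraction == 0.0

    def test_realisation_consumes_single_stream_in_order(self, toy):
        s = nlmc.RandomStream(3)
        real = nlmc.nlmc_realisation(
            toy, nlmc.reciprocal_kernel(1.0), nlmc.geometric_degree(1.0), s
        )
        assert s.position == 2 + real.degree
        assert real.inner_draws.size == real.degree
        # replaying the same uniforms reproduces the tuple
        s2 = nlmc.RandomStream(3)
        assert float(toy.outer_from_uniform(s2.uniform())) == real.y


class TestPluginEstimate:
    def test_k_one_exhibits_plugin_bias(self, toy, stream):
        """At K=1 the plug-in targets E_Y E_X[1/(1+X)] = pi^2/12, not 2 ln 1.5."""
        rep = nlmc.plugin_estimate(toy, lambda x: 1 / (1 + x), 1, 400_000, stream)
        assert _z(rep, math.pi**2 / 12.0) < 4
        # ... which is 14 sigma away from the true nested value here
        assert _z(rep, nlmc.TOY_EXACT) > 10

    def test_bias_shrinks_with_k(self, toy):
        """O(1/K) bias: common random numbers, |bias(K=10)| > |bias(K=1000)|."""
        f = lambda x: 1 / (1 + x)
        b = {}
        for K in (10, 1000):
            rep = nlmc.plugin_estimate(toy, f, K, 200_000, nlmc.RandomStream(11))
            b[K] = rep.estimate - nlmc.TOY_EXACT
        assert abs(b[10]) > abs(b[1000])

    def test_large_k_bias_below_noise(self, toy, stream):
        rep = nlmc.plugin_estimate(toy, lambda x: 1 / (1 + x), 3333, 10_000, stream)
        assert _z(rep, nlmc.TOY_EXACT) < 4

    def test_generation_accounting(self, toy, stream):
        rep = nlmc.plugin_estimate(toy, lambda x: 1 / (1 + x), 7, 5000, stream)
        assert rep.generations.outer == 5000
        assert rep.generations.inner == 7 * 5000
        assert rep.cost == 5000 * 8

    def test_zero_inner_samples_rejected(self, toy, stream):
        with pytest.raises(ValueError, match="K must be >= 1"):
            nlmc.plugin_estimate(toy, lambda x: x, 0, 100, stream)


class TestHeavyTailWatchdog:
    def test_tail_dominated_weights_trigger_warning(self):
        """When a rare outcome carries nearly all the |weight| mass, the
        top-1% mass-share watchdog must fire and flag the report."""
        skewed = nlmc.DiscreteProblem(
            "skewed", [0.0, 1.0], [0.999, 0.001],
            lambda r: np.where(np.asarray(r) == 0.0, 1e-3, 1e3),
        )
        with pytest.warns(nlmc.HeavyTailWarning):
            rep = nlmc.discrete_estimate(skewed, 50_000, nlmc.RandomStream(13))
        assert rep.heavy_tailed
        assert rep.top_mass_share > 0.5

    def test_share_grows_as_x0_shrinks(self, toy):
        """In the small-x0 near-divergent-variance regime the |weight| mass
        concentrates into the extreme realisations."""
        shares = {}
        for x0 in (0.125, 1.0):
            rep = nlmc.nlmc_estimate(
                toy, nlmc.reciprocal_kernel(x0), nlmc.geometric_degree(x0),
                100_000, nlmc.RandomStream(13),
            )
            shares[x0] = rep.top_mass_share
        assert shares[0.125] > 2 * shares[1.0]


class TestPairIdentity:
    """E_Y(E[X|Y]^2) via i.i.d. pairs equals the quadrature oracle of
    E_Y(Z_Y^2) across distinct problems."""

    @pytest.mark.parametrize("factory,scale", [
        (nlmc.make_toy_problem, 1.0),
        (nlmc.make_expdemo_problem, 1.0),
        (lambda: nlmc.NestedProblem(
            name="shifted",
            outer_from_uniform=lambda u: 1.0 + np.asarray(u, float),
            conditional_from_uniform=lambda y, u: y * np.asarray(u, float),
            outer_support=(1.0, 2.0),
            conditional_support=lambda y: (0.0, y),
            conditional_mean=lambda y: 0.5 * np.asarray(y, float),
            outer_density=lambda y: np.where(
                (np.asarray(y, float) >= 1) & (np.asarray(y, float) <= 2), 1.0, 0.0),
        ), 1.0),
    ])
    def test_pair_product_matches_oracle(self, factory, scale):
        problem = factory()
        oracle = nlmc.quadrature_nested_expectation(
            problem, lambda z: z * z
        )
        rep = nlmc.monomial_product_estimate(problem, 2, 200_000, nlmc.RandomStream(17))
        assert abs(rep.estimate - oracle.value) < 4 * rep.standard_error
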