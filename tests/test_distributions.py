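import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tcrtail import (
    DiscreteGamma,
    DiscreteGPD,
    SplicedDistribution,
    gpd_cdf_continuous,
)


class TestDiscreteGamma:
    def test_alpha_one_is_discretized_exponential(self):
        # alpha=1 reduces to e^(-beta x) - e^(-beta (x+1))
        dg = DiscreteGamma(1.0, 0.5)
        assert dg.pmf(0) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        assert dg.pmf(7) == pytest.approx(math.exp(-3.5) - math.exp(-4.0), abs=1e-12)
        assert dg.cdf(0) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)

    def test_normalization(self):
        dg = DiscreteGamma(3.0, 0.15)
        assert dg.pmf(np.arange(0, 10_001)).sum() == pytest.approx(1.0, abs=1e-8)

    def test_pmf_matches_floor_of_continuous_draws(self):
        # the quantized Gamma is exactly the law of floor(Y), Y ~ Gamma
        rng = np.random.default_rng(7)
        draws = np.floor(stats.gamma.rvs(3.0, scale=1 / 0.15, size=1_000_000,
                                         random_state=rng))
        emp = np.mean(draws == 10)
        p = float(DiscreteGamma(3.0, 0.15).pmf(10))
        se = math.sqrt(p * (1 - p) / 1_000_000)
        assert abs(emp - p) < 4 * se

    def test_cdf_equals_continuous_cdf_at_x_plus_one(self):
        dg = DiscreteGamma(3.0, 0.15)
        expected = stats.gamma.cdf(6.0, 3.0, scale=1 / 0.15)
        assert dg.cdf(5) == pytest.approx(expected, abs=1e-12)
        assert dg.cdf(100_000) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters_and_domain(self):
        with pytest.raises(ValueError):
            DiscreteGamma(0.0, 1.0)
        with pytest.raises(ValueError):
            DiscreteGamma(1.0, -2.0)
        with pytest.raises(ValueError):
            DiscreteGamma(1.0, 1.0).pmf(-1)
        with pytest.raises(ValueError):
            DiscreteGamma(1.0, 1.0).pmf(1.5)


class TestDiscreteGPD:
    def test_closed_form_xi_one(self):
        # u=0, sigma=1, xi=1: S(x) = 1/(1+x), pmf(x) = 1/(1+x) - 1/(2+x)
        g = DiscreteGPD(0, 1.0, 1.0)
        assert g.pmf(0) == pytest.approx(0.5, abs=1e-12)
        assert g.pmf(3) == pytest.approx(1 / 4 - 1 / 5, abs=1e-12)

    def test_exponential_limit_branch(self):
        g = DiscreteGPD(0, 2.0, 1e-12)
        assert g.pmf(3) == pytest.approx(math.exp(-1.5) - math.exp(-2.0), abs=1e-12)

    @pytest.mark.parametrize("xi", [1e-9, -1e-9])
    def test_xi_to_zero_continuity(self, xi):
        near = DiscreteGPD(5, 4.0, xi)
        limit = DiscreteGPD(5, 4.0, 0.0)
        xs = np.arange(5, 60)
        assert np.max(np.abs(near.pmf(xs) - limit.pmf(xs))) < 1e-8

    @pytest.mark.parametrize("params", [(5, 4.0, 0.5), (1, 2.0, 0.0), (3, 10.0, -0.4)])
    def test_normalization(self, params):
        g = DiscreteGPD(*params)
        upper = g.truncation_point(1e-10)
        xs = np.arange(g.u, upper + 1)
        assert g.pmf(xs).sum() == pytest.approx(1.0, abs=1e-8)

    def test_negative_xi_support_is_bounded(self):
        g = DiscreteGPD(3, 10.0, -0.4)
        # continuous bound u - sigma/xi = 28
        assert g.support_max == 27
        assert g.cdf(g.support_max) == pytest.approx(1.0, abs=1e-12)
        assert g.pmf(g.support_max + 1) == 0.0

    def test_quantile_endpoints_and_scan_oracle(self):
        g = DiscreteGPD(5, 4.0, 0.5)
        assert g.quantile(0.0) == 5
        # independent oracle: linear scan of cumulative pmf sums
        xs = np.arange(5, 4000)
        cum = np.cumsum(g.pmf(xs))
        expected = xs[np.searchsorted(cum, 0.9)]
        assert g.quantile(0.9) == expected
        with pytest.raises(ValueError):
            g.quantile(1.0)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        u=st.integers(0, 30),
        sigma=st.floats(0.2, 50.0),
        xi=st.floats(-0.9, 2.0),
        p=st.floats(0.0, 0.9999),
    )
    def test_quantile_cdf_galois(self, u, sigma, xi, p):
        g = DiscreteGPD(u, sigma, xi)
        x = int(g.quantile(p))
        assert g.cdf(x) >= p
        if x > u:
            assert g.cdf(x - 1) < p

    def test_sampling_matches_pmf(self):
        g = DiscreteGPD(5, 4.0, 0.5)
        rng = np.random.default_rng(11)
        draws = g.rvs(1_000_000, rng)
        top = int(np.quantile(draws, 0.999))
        edges = np.arange(5, top + 1)
        obs = np.concatenate([
            np.bincount(np.clip(draws, None, top), minlength=top + 1)[5:top],
            [np.sum(draws >= top)],
        ])
        exp = np.concatenate([g.pmf(edges[:-1]), [float(g.sf(top - 1))]]) * draws.size
        res = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert res.pvalue > 0.01


class TestThresholdStability:
    @pytest.mark.parametrize("u", [0, 3, 10])
    @pytest.mark.parametrize("sigma,xi", [(4.0, 0.5), (10.0, 0.05), (2.0, 1.2),
                                          (10.0, -0.3), (6.0, -0.05)])
    def test_discrete_excess_law(self, u, sigma, xi):
        # conditioning on exceeding u shifts the discrete GPD to threshold 0
        # with scale sigma + xi and the same shape
        g = DiscreteGPD(u, sigma, xi)
        shifted = DiscreteGPD(0, sigma + xi, xi)
        if xi < 0:
            xmax = min(int(shifted.support_max), 40) - 1
        else:
            xmax = 40
        xs = np.arange(0, max(xmax, 1))
        lhs = (g.cdf(xs + u + 1) - g.cdf(u)) / (1.0 - g.cdf(u))
        rhs = shifted.cdf(xs)
        assert np.max(np.abs(lhs - rhs)) < 1e-10


class TestParetoEquivalence:
    @pytest.mark.parametrize("u", [1.0, 10.0, 120.0])
    @pytest.mark.parametrize("alpha_d", [0.5, 1.0, 2.5, 6.0])
    def test_gpd_special_case_is_type_one_pareto(self, u, alpha_d):
        x = np.linspace(u, 50 * u, 500)
        gpd = gpd_cdf_continuous(x, u, u / alpha_d, 1.0 / alpha_d)
        pareto = 1.0 - (u / x) ** alpha_d
        assert np.max(np.abs(gpd - pareto)) < 1e-10


class TestSplicedDistribution:
    def test_bulk_mass_is_one_minus_phi(self, reference_model):
        m = reference_model
        xs = np.arange(1, m.u)
        assert m.pmf(xs).sum() == pytest.approx(1 - m.phi, abs=1e-8)
        assert m.cdf(m.u - 1) == pytest.approx(1 - m.phi, abs=1e-12)

    def test_total_mass(self, reference_model):
        m = reference_model
        xs = np.arange(1, m.support_upper(1e-10) + 1)
        assert m.pmf(xs).sum() == pytest.approx(1.0, abs=1e-8)

    def test_phi_one_degenerates_to_tail(self):
        tail = DiscreteGPD(5, 4.0, 0.5)
        m = SplicedDistribution(DiscreteGamma(3.0, 0.15), tail, 1.0)
        xs = np.arange(5, 200)
        assert np.allclose(m.pmf(xs), tail.pmf(xs), atol=1e-15)
        assert np.all(m.pmf(np.arange(1, 5)) == 0.0)

    def test_pmf_composes_from_components(self, reference_model):
        # independent recomposition from scipy special functions
        from scipy import special

        m = reference_model
        a, b, u, phi = 3.0, 0.15, 20, 0.15
        h3 = special.gammainc(a, b * 4) - special.gammainc(a, b * 3)
        z = special.gammainc(a, b * u) - special.gammainc(a, b * 1)
        assert m.pmf(3) == pytest.approx((1 - phi) * h3 / z, rel=1e-12)
        s25 = (1 + 0.5 * (25 - 20) / 20.0) ** -2 - (1 + 0.5 * (26 - 20) / 20.0) ** -2
        assert m.pmf(25) == pytest.approx(phi * s25, rel=1e-12)

    def test_literal_normalizer_includes_zero(self):
        m = SplicedDistribution(DiscreteGamma(3.0, 0.15), DiscreteGPD(20, 20.0, 0.5),
                                0.15, bulk_includes_zero=True)
        xs = np.arange(0, m.u)
        assert m.pmf(xs).sum() == pytest.approx(1 - m.phi, abs=1e-8)
        # left-truncated variant redistributes the mass at 0 over 1..u-1
        trunc = SplicedDistribution(m.bulk, m.tail, m.phi)
        assert float(trunc.pmf(3)) > float(m.pmf(3))

    def test_cdf_monotone_and_limits(self, reference_model):
        m = reference_model
        xs = np.arange(1, 2000)
        cdf = m.cdf(xs)
        assert np.all(np.diff(cdf) >= -1e-15)
        assert m.cdf(m.support_upper(1e-13)) == pytest.approx(1.0, abs=1e-8)

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            SplicedDistribution(DiscreteGamma(3, 0.15), DiscreteGPD(20, 20, 0.5), 1.2)
        with pytest.raises(ValueError):
            SplicedDistribution(DiscreteGamma(3, 0.15), DiscreteGPD(1, 20, 0.5), 0.5)


class TestSplicedLoglik:
    def test_toy_sample_composes_from_pmf_logs(self, reference_model):
        sample = np.array([1, 1, 2, 20, 35])
        expected = float(np.sum(np.log(reference_model.pmf(sample))))
        assert reference_model.loglik(sample) == pytest.approx(expected, rel=1e-12)

    def test_single_clone_at_threshold(self, reference_model):
        m = reference_model
        expected = math.log(m.phi * float(m.tail.pmf(m.u)))
        assert m.loglik([m.u]) == pytest.approx(expected, rel=1e-12)

    def test_zero_mass_observation_gives_minus_inf(self):
        m = SplicedDistribution(DiscreteGamma(3, 0.15), DiscreteGPD(10, 4.0, -0.5), 0.2)
        beyond = int(m.tail.support_max) + 1
        assert m.loglik([5, beyond]) == -math.inf

    def test_empty_sample_rejected(self, reference_model):
        with pytest.raises(ValueError):
            reference_model.loglik([])

    def test_true_params_beat_perturbed_on_model_draws(self, reference_model,
                                                       simulated_sample):
        m = reference_model
        counts = simulated_sample.counts
        ll_true = m.loglik(counts) / counts.size
        for dxi in (0.3, -0.3):
            pert = SplicedDistribution(
                m.bulk, DiscreteGPD(m.u, m.tail.sigma, m.tail.xi + dxi), m.phi)
            assert ll_true > pert.loglik(counts) / counts.size
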