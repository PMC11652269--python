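import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from sgsearch.gumbel import (GumbelParams, HSPModel, fit_gumbel_mle,
                             fit_gumbel_mle_batch, gumbel_cdf, gumbel_density,
                             gumbel_quantile, gumbel_tail, hsp_evalue,
                             hsp_pvalue, max_gumbel_location, sample_gumbel)

STD = GumbelParams(0.0, 1.0)


class TestGumbelPrimitives:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            GumbelParams(0.0, 0.0)
        with pytest.raises(ValueError):
            GumbelParams(float("nan"), 1.0)

    @pytest.mark.parametrize("p", [STD, GumbelParams(2.0, 0.5), GumbelParams(-3.0, 4.0)])
    def test_density_at_location(self, p):
        # substituting x = mu gives lam * e^{-1}
        assert gumbel_density(p.mu, p) == pytest.approx(p.lam * math.exp(-1), rel=1e-14)

    def test_density_frozen_values(self):
        assert gumbel_density(0.0, STD) == pytest.approx(math.exp(-1), rel=1e-14)
        # arbitrary-precision evaluation of the formula at mu=0, lam=1/3, x=33
        assert gumbel_density(33.0, GumbelParams(0.0, 1 / 3)) == pytest.approx(
            5.56714061525526750806895265785e-06, rel=1e-13)

    def test_density_integrates_to_one(self):
        p = GumbelParams(1.5, 0.7)
        val, err = integrate.quad(lambda x: gumbel_density(x, p), -30, 60)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_tail_frozen_values(self):
        assert gumbel_tail(0.0, STD) == pytest.approx(1 - math.exp(-1), rel=1e-14)
        assert gumbel_tail(3.0, STD) == pytest.approx(
            0.0485680070995465927084983971176, rel=1e-13)

    def test_tail_limits_and_monotonicity(self):
        assert gumbel_tail(1e4, STD) == pytest.approx(0.0, abs=1e-300)
        assert gumbel_tail(-40.0, STD) == pytest.approx(1.0, rel=1e-15)
        x = np.linspace(-2, 10, 301)  # inside the range where tail < 1 in floats
        t = gumbel_tail(x, STD)
        assert np.all(np.diff(t) < 0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            gumbel_tail(float("inf"), STD)
        with pytest.raises(ValueError):
            gumbel_density(float("nan"), STD)

    @given(q=st.floats(1e-12, 1 - 1e-12), mu=st.floats(-50, 50),
           lam=st.floats(0.01, 20))
    @settings(max_examples=200, deadline=None)
    def test_quantile_tail_round_trip(self, q, mu, lam):
        p = GumbelParams(mu, lam)
        assert gumbel_cdf(gumbel_quantile(q, p), p) == pytest.approx(q, abs=1e-12)


class TestSampling:
    def test_count_validation(self):
        with pytest.raises(ValueError):
            sample_gumbel(0, STD, 1)

    def test_reproducible(self):
        a = sample_gumbel(100, STD, 42)
        b = sample_gumbel(100, STD, 42)
        np.testing.assert_array_equal(a, b)

    def test_moments_and_gof(self):
        p = GumbelParams(5.0, 0.5)
        x = sample_gumbel(10**5, p, 7)
        se_mean = math.sqrt(p.variance / x.size)
        assert x.mean() == pytest.approx(p.mean, abs=4 * se_mean)
        assert x.var(ddof=1) == pytest.approx(p.variance, rel=0.05)
        ks = stats.kstest(x, lambda v: gumbel_cdf(v, p))
        assert ks.pvalue > 0.01


class TestMLEFit:
    def test_location_equivariance(self):
        x = sample_gumbel(4000, STD, 3)
        base = fit_gumbel_mle(x)
        shifted = fit_gumbel_mle(x + 11.5)
        assert shifted.mu == pytest.approx(base.mu + 11.5, abs=1e-7)
        assert shifted.lam == pytest.approx(base.lam, rel=1e-9)

    def test_scale_equivariance(self):
        x = sample_gumbel(4000, STD, 4)
        base = fit_gumbel_mle(x)
        scaled = fit_gumbel_mle(2.5 * x)
        assert scaled.lam == pytest.approx(base.lam / 2.5, rel=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gumbel_mle(np.full(10, 3.0))

    def test_matches_scipy_mle(self):
        x = sample_gumbel(5000, GumbelParams(2.0, 1 / 3), 5)
        ours = fit_gumbel_mle(x)
        loc, scale = stats.gumbel_r.fit(x)
        assert ours.mu == pytest.approx(loc, rel=1e-4)
        assert 1 / ours.lam == pytest.approx(scale, rel=1e-4)

    @pytest.mark.parametrize("mu,lam", [(0.0, 1.0), (2.0, 1 / 3), (-5.0, 4.0)])
    def test_recovery_within_3se(self, mu, lam):
        # asymptotic SDs of the Gumbel MLEs (Fisher information)
        n = 20_000
        x = sample_gumbel(n, GumbelParams(mu, lam), seed=hash((mu, lam)) % 2**31)
        fit = fit_gumbel_mle(x)
        beta = 1 / lam
        se_mu = beta * math.sqrt(1 + 6 * (1 - np.euler_gamma)**2 / math.pi**2) / math.sqrt(n)
        se_beta = beta * math.sqrt(6 / math.pi**2) / math.sqrt(n)
        assert abs(fit.mu - mu) < 3 * se_mu
        assert abs(1 / fit.lam - beta) < 3 * se_beta

    def test_batch_fit_agrees_with_single(self):
        rows = np.stack([sample_gumbel(60, GumbelParams(1.0, 0.5), s) for s in range(8)])
        mu, lam = fit_gumbel_mle_batch(rows)
        for i in range(8):
            single = fit_gumbel_mle(rows[i])
            assert mu[i] == pytest.approx(single.mu, abs=1e-7)
            assert lam[i] == pytest.approx(single.lam, rel=1e-7)


class TestHSPFormulas:
    MODEL = HSPModel(K=0.04, lam=0.27, n=100, l=300, L=10**6, N=2)

    def test_pvalue_half(self):
        # s solving K n l e^{-lam s} = ln 2 makes the P-value exactly 1/2
        s = math.log(0.04 * 100 * 300 / math.log(2)) / 0.27
        assert hsp_pvalue(s, self.MODEL) == pytest.approx(0.5, rel=1e-12)

    def test_pvalue_frozen(self):
        assert hsp_pvalue(40.0, self.MODEL) == pytest.approx(
            0.0241822134365734768138702635586, rel=1e-12)
        assert hsp_pvalue(1e5, self.MODEL) == 0.0

    def test_evalue_frozen(self):
        assert hsp_evalue(60.0, self.MODEL) == pytest.approx(
            0.368544033382645122073320579485, rel=1e-12)

    def test_evalue_single_sequence_database(self):
        m = HSPModel(K=0.04, lam=0.27, n=100, l=500, L=500, N=1)
        assert hsp_evalue(30.0, m) == hsp_evalue(30.0, m, per_sequence=True)

    def test_evalue_additive_in_length(self):
        whole = HSPModel(K=0.04, lam=0.27, n=100, L=900)
        parts = [HSPModel(K=0.04, lam=0.27, n=100, L=400),
                 HSPModel(K=0.04, lam=0.27, n=100, L=500)]
        assert hsp_evalue(25.0, whole) == pytest.approx(
            sum(hsp_evalue(25.0, p) for p in parts), rel=1e-12)

    def test_pvalue_below_evalue(self):
        m = HSPModel(K=0.04, lam=0.27, n=100, l=300, L=300)
        for s in np.linspace(0, 80, 50):
            assert hsp_pvalue(s, m) <= hsp_evalue(s, m) + 1e-15


class TestMaxStability:
    def test_single_location(self):
        assert max_gumbel_location([4.2], 1.3) == pytest.approx(4.2, rel=1e-12)

    def test_identical_locations(self):
        lam = 0.7
        assert max_gumbel_location([2.0] * 8, lam) == pytest.approx(
            2.0 + math.log(8) / lam, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_gumbel_location([], 1.0)

    def test_dominates_max_location(self):
        assert max_gumbel_location([0.0, 2.0, -1.0], 1.0) >= 2.0

    def test_simulated_max_distribution(self):
        # max of Gumbel(0,1) and Gumbel(2,1) should be Gumbel(nu, 1)
        nu = max_gumbel_location([0.0, 2.0], 1.0)
        rng = np.random.default_rng(99)
        n = 20_000
        a = -np.log(-np.log(rng.random(n)))
        b = 2.0 - np.log(-np.log(rng.random(n)))
        mx = np.maximum(a, b)
        ks = stats.kstest(mx, lambda v: gumbel_cdf(v, GumbelParams(nu, 1.0)))
        assert ks.pvalue > 0.01
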