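"""Skew-normal core: CP/DP bijection, densities, CDF, quantiles, sampling.

Oracles: adaptive quadrature of the DP density for moments and tail
probabilities, and scipy.stats.skewnorm (an independent implementation of
the DP form) for cross-checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from skewmaps.skewnorm import (
    C_GAMMA,
    CPParams,
    DPParams,
    cp_to_dp,
    cp_to_dp_arrays,
    dp_to_cp,
    dp_to_cp_arrays,
    sample_sn,
    skewness_bound,
    sn_cdf,
    sn_pdf,
    sn_quantile,
)


def dp_pdf(x, xi, omega, alpha):
    z = (x - xi) / omega
    return 2.0 / omega * stats.norm.pdf(z) * stats.norm.cdf(alpha * z)


def dp_moments_by_quadrature(xi, omega, alpha):
    lo, hi = xi - 14 * omega, xi + 14 * omega
    m0 = integrate.quad(lambda x: dp_pdf(x, xi, omega, alpha), lo, hi, limit=200)[0]
    m1 = integrate.quad(lambda x: x * dp_pdf(x, xi, omega, alpha), lo, hi, limit=200)[0]
    m2 = integrate.quad(
        lambda x: (x - m1) ** 2 * dp_pdf(x, xi, omega, alpha), lo, hi, limit=200
    )[0]
    m3 = integrate.quad(
        lambda x: (x - m1) ** 3 * dp_pdf(x, xi, omega, alpha), lo, hi, limit=200
    )[0]
    assert abs(m0 - 1) < 1e-9
    return m1, np.sqrt(m2), m3 / m2 ** 1.5


class TestBoundAndTypes:
    def test_bound_value(self):
        assert skewness_bound() == pytest.approx(0.9953, abs=5e-5)
        assert skewness_bound() < 1.0

    def test_bound_is_limit_of_dp_skewness(self):
        # moment skewness of DP with alpha -> +inf approaches the bound
        _, _, gamma = dp_to_cp_arrays(0.0, 1.0, 1e8)
        assert float(gamma) == pytest.approx(skewness_bound(), abs=1e-4)

    @pytest.mark.parametrize("gamma", [C_GAMMA, -C_GAMMA, 0.9953, 1.2])
    def test_gamma_at_or_over_bound_rejected(self, gamma):
        with pytest.raises(ValueError, match="gamma"):
            CPParams(mu=0.0, sigma=1.0, gamma=gamma)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            CPParams(mu=0.0, sigma=0.0, gamma=0.1)
        with pytest.raises(ValueError):
            DPParams(xi=0.0, omega=-1.0, alpha=0.0)


class TestBijection:
    def test_symmetric_case_collapses_to_normal(self):
        dp = cp_to_dp(CPParams(0.0, 1.0, 0.0))
        assert (dp.xi, dp.omega, dp.alpha) == (0.0, 1.0, 0.0)
        cp = dp_to_cp(DPParams(0.0, 1.0, 0.0))
        assert (cp.mu, cp.sigma, cp.gamma) == (0.0, 1.0, 0.0)

    def test_alpha_sign_fixes_gamma_sign(self):
        cp_pos = dp_to_cp(DPParams(0.0, 1.0, 5.0))
        assert 0.0 < cp_pos.gamma < skewness_bound()
        cp_neg = dp_to_cp(DPParams(0.0, 1.0, -5.0))
        assert cp_neg.gamma == pytest.approx(-cp_pos.gamma)

    @pytest.mark.parametrize(
        "cp", [CPParams(1000.0, 50.0, 0.5), CPParams(-3.0, 0.2, -0.8), CPParams(0.0, 1.0, 0.95)]
    )
    def test_cp_moments_match_quadrature(self, cp):
        dp = cp_to_dp(cp)
        mean, sd, skew = dp_moments_by_quadrature(dp.xi, dp.omega, dp.alpha)
        assert mean == pytest.approx(cp.mu, rel=1e-6, abs=1e-6)
        assert sd == pytest.approx(cp.sigma, rel=1e-6)
        assert skew == pytest.approx(cp.gamma, rel=1e-6, abs=1e-6)

    def test_dp_moments_match_quadrature(self):
        cp = dp_to_cp(DPParams(2.0, 3.0, -4.0))
        mean, sd, skew = dp_moments_by_quadrature(2.0, 3.0, -4.0)
        assert cp.mu == pytest.approx(mean, rel=1e-6)
        assert cp.sigma == pytest.approx(sd, rel=1e-6)
        assert cp.gamma == pytest.approx(skew, rel=1e-6)

    def test_roundtrip_1000_random_triples(self):
        rng = np.random.default_rng(42)
        mu = rng.uniform(-1000, 1000, 1000)
        sigma = 10 ** rng.uniform(-2, 3, 1000)
        gamma = rng.uniform(-0.99, 0.99, 1000) * C_GAMMA
        xi, omega, alpha = cp_to_dp_arrays(mu, sigma, gamma)
        mu2, sigma2, gamma2 = dp_to_cp_arrays(xi, omega, alpha)
        for a, b in [(mu, mu2), (sigma, sigma2), (gamma, gamma2)]:
            rel = np.abs(a - b) / np.maximum(np.abs(a), 1e-8)
            assert rel.max() < 1e-10

    @given(
        xi=st.floats(-100, 100),
        omega=st.floats(0.01, 100),
        alpha=st.floats(-50, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_dp_roundtrip_property(self, xi, omega, alpha):
        mu, sigma, gamma = dp_to_cp_arrays(xi, omega, alpha)
        xi2, omega2, alpha2 = cp_to_dp_arrays(mu, sigma, gamma)
        assert float(xi2) == pytest.approx(xi, rel=1e-9, abs=1e-9)
        assert float(omega2) == pytest.approx(omega, rel=1e-9)
        assert float(alpha2) == pytest.approx(alpha, rel=1e-8, abs=1e-8)


class TestCdfPdf:
    def test_normal_reduction(self):
        cp = CPParams(3.0, 2.0, 0.0)
        x = np.linspace(-5, 11, 41)
        assert np.abs(sn_cdf(x, cp) - stats.norm.cdf((x - 3) / 2)).max() < 1e-12
        assert np.abs(sn_pdf(x, cp) - stats.norm.pdf(x, 3, 2)).max() < 1e-12
        assert sn_cdf(3.0, cp) == pytest.approx(0.5, abs=1e-14)

    def test_cdf_matches_quadrature(self):
        cp = CPParams(1000.0, 50.0, 0.5)
        dp = cp_to_dp(cp)
        ref = integrate.quad(
            lambda t: dp_pdf(t, dp.xi, dp.omega, dp.alpha), dp.xi - 14 * dp.omega, 1050.0,
            limit=200,
        )[0]
        assert float(sn_cdf(1050.0, cp)) == pytest.approx(ref, abs=1e-8)

    def test_cdf_matches_scipy_skewnorm(self):
        # independent DP implementation as cross-check
        cp = CPParams(-1.0, 2.5, -0.7)
        dp = cp_to_dp(cp)
        x = np.linspace(-12, 10, 23)
        ref = stats.skewnorm.cdf(x, dp.alpha, loc=dp.xi, scale=dp.omega)
        assert np.abs(sn_cdf(x, cp) - ref).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_cdf_equals_pdf_quadrature_random_params(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            cp = CPParams(
                rng.uniform(-10, 10), 10 ** rng.uniform(-1, 1), rng.uniform(-0.9, 0.9) * C_GAMMA
            )
            x = cp.mu + cp.sigma * rng.uniform(-3, 3)
            dp = cp_to_dp(cp)
            ref = integrate.quad(
                lambda t: dp_pdf(t, dp.xi, dp.omega, dp.alpha),
                dp.xi - 14 * dp.omega,
                x,
                limit=200,
            )[0]
            assert float(sn_cdf(x, cp)) == pytest.approx(ref, abs=1e-8)

    def test_cdf_monotone_and_bounded(self):
        cp = CPParams(0.0, 1.0, 0.9)
        x = np.linspace(-8, 8, 500)
        u = sn_cdf(x, cp)
        # nondecreasing up to the ~1e-16 cancellation noise of Owen's T
        assert np.all(np.diff(u) >= -1e-15)
        # strictly increasing wherever the CDF exceeds that noise floor
        interior = (u > 1e-14) & (u < 1 - 1e-14)
        assert np.all(np.diff(u[interior]) > 0)
        assert u.min() >= 0 and u.max() <= 1
        assert float(sn_cdf(-np.inf, cp)) == 0.0
        assert float(sn_cdf(np.inf, cp)) == 1.0

    def test_gamma_to_zero_continuity(self):
        x = np.linspace(-6, 6, 200)
        u_eps = sn_cdf(x, CPParams(0.0, 1.0, 1e-6))
        u_0 = stats.norm.cdf(x)
        assert np.abs(u_eps - u_0).max() < 1e-5

    def test_pdf_normalises(self):
        for cp in [CPParams(0.0, 1.0, 0.8), CPParams(5.0, 0.3, -0.5)]:
            total = integrate.quad(
                lambda t: float(sn_pdf(t, cp)), cp.mu - 10 * cp.sigma, cp.mu + 10 * cp.sigma,
                limit=200,
            )[0]
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_pdf_positive_at_median(self):
        cp = CPParams(2.0, 1.5, 0.6)
        assert float(sn_pdf(sn_quantile(0.5, cp), cp)) > 0


class TestQuantile:
    def test_median_of_symmetric_is_mu(self):
        assert float(sn_quantile(0.5, CPParams(7.0, 3.0, 0.0))) == pytest.approx(7.0, abs=1e-9)

    @pytest.mark.parametrize("gamma", [0.0, 0.5, -0.9])
    def test_roundtrip(self, gamma):
        cp = CPParams(10.0, 4.0, gamma)
        p = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert np.abs(sn_cdf(sn_quantile(p, cp), cp) - p).max() < 1e-9

    def test_right_skew_widens_upper_spacing(self):
        cp = CPParams(0.0, 1.0, 0.9)
        q = sn_quantile(np.array([0.1, 0.3, 0.7, 0.9]), cp)
        assert (q[3] - q[2]) > (q[1] - q[0])

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValueError):
            sn_quantile(p, CPParams(0.0, 1.0, 0.0))


class TestSampling:
    def test_moments_converge(self):
        cp = CPParams(0.0, 1.0, 0.5)
        x = sample_sn(10 ** 6, cp, seed=3)
        assert x.mean() == pytest.approx(0.0, abs=0.01)
        assert x.std() == pytest.approx(1.0, abs=0.01)
        assert stats.skew(x) == pytest.approx(0.5, abs=0.02)

    def test_normal_reduction_ks(self):
        x = sample_sn(10 ** 4, CPParams(5.0, 2.0, 0.0), seed=4)
        assert stats.kstest(x, stats.norm(5.0, 2.0).cdf).pvalue > 0.01

    def test_seed_determinism(self):
        cp = CPParams(1.0, 2.0, -0.3)
        assert np.array_equal(sample_sn(1000, cp, seed=9), sample_sn(1000, cp, seed=9))

    def test_n_validation(self):
        with pytest.raises(ValueError):
            sample_sn(0, CPParams(0.0, 1.0, 0.0), seed=1)
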