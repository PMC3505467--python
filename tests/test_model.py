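import math

import numpy as np
import pytest
from scipy import integrate, stats

from gelbayes import (
    GlobalParams,
    LocalParams,
    ModelConstants,
    expression_prob,
    global_layer_log_lik,
    global_log_prior,
    joint_log_posterior,
    mod_laplace_log_pdf,
    spot_log_lik,
    spot_obs_log_lik,
    truncnorm_mass,
)
from gelbayes.model import local_log_lik_all

from _reference import ref_joint_log_posterior, ref_mod_laplace_logpdf, ref_truncnorm_mass

D, NU = -8.67, math.log2(100.0)

GLOBALS = GlobalParams(
    mu_g=-5.0, sigma_g=1.0, psi=0.7, lambda_delta=0.5, phi_delta=0.5,
    mu_kappa=1.0, sigma_kappa=1.0, mu_tau=0.0, sigma_tau=2.0,
)


class TestExpressionProb:
    def test_symmetry_and_anchor(self):
        assert expression_prob(0.0) == 0.5
        # kappa ~ 2.94 corresponds to 95% expression probability
        assert abs(expression_prob(2.94) - 0.95) < 0.001

    def test_tau_zero_is_identity(self):
        k = np.linspace(-3, 3, 7)
        assert np.array_equal(expression_prob(k, np.zeros(7)), expression_prob(k))

    def test_saturates_without_overflow(self):
        assert expression_prob(800.0) == 1.0
        assert expression_prob(-800.0) == 0.0
        assert 0.0 < expression_prob(-30.0) < 1e-12


class TestTruncnormMass:
    def test_full_support_is_one(self):
        assert np.isclose(truncnorm_mass(0.0, 1.0, -1e9, 1e9), 1.0)

    def test_symmetric_window(self):
        lam = truncnorm_mass((D + NU) / 2.0, 2.0, D, NU)
        a = (NU - D) / 2.0 / 2.0
        assert np.isclose(lam, stats.norm.cdf(a) - stats.norm.cdf(-a))

    def test_matches_quadrature(self):
        val, _ = integrate.quad(lambda y: stats.norm.pdf(y, -5.0, 0.7), D, NU)
        assert abs(truncnorm_mass(-5.0, 0.7, D, NU) - val) < 1e-12

    def test_deep_tail_no_cancellation(self):
        # window far above the mean: difference of survival functions
        mu = NU + 10.0
        expect = stats.norm.sf(D, mu, 0.7) - stats.norm.sf(NU, mu, 0.7)
        got = truncnorm_mass(mu, 0.7, D, NU)
        assert got > 0.0
        assert np.isclose(got, expect, rtol=1e-10)
        # and far below
        mu = D - 10.0
        expect = stats.norm.cdf(NU, mu, 0.7) - stats.norm.cdf(D, mu, 0.7)
        assert np.isclose(truncnorm_mass(mu, 0.7, D, NU), expect, rtol=1e-10)


class TestSpotObsLogLik:
    def test_nonexpressed_missing_is_certain(self):
        assert spot_obs_log_lik(None, -5.0, 0.7, 0.0, D, NU) == 0.0

    def test_normal_peak_density_one(self):
        sigma = 1.0 / math.sqrt(2.0 * math.pi)
        val = spot_obs_log_lik(0.0, 0.0, sigma, 1.0, -1e9, 1e9)
        assert abs(val) < 1e-12

    def test_observed_branch_matches_quadrature_normaliser(self):
        lam = ref_truncnorm_mass(-5.0, 0.7, D, NU)
        expect = math.log(0.8) + stats.norm.logpdf(-5.0, -5.0, 0.7) - math.log(lam)
        assert abs(spot_obs_log_lik(-5.0, -5.0, 0.7, 0.8, D, NU) - expect) < 1e-12

    def test_rejects_value_above_nu(self):
        with pytest.raises(ValueError):
            spot_obs_log_lik(NU + 0.5, -5.0, 0.7, 0.8, D, NU)

    def test_total_mass_identity(self):
        # the observed branch integrates to rho over [d, nu]; the missing
        # branch carries (1 - rho) + rho * Phi((d - mu)/sigma) with the
        # untruncated CDF, so the total mass is 1 + rho * Phi((d - mu)/sigma)
        mu, sigma, rho = -6.5, 0.9, 0.8
        obs, _ = integrate.quad(
            lambda c: math.exp(spot_obs_log_lik(c, mu, sigma, rho, D, NU)), D, NU
        )
        missing = math.exp(spot_obs_log_lik(None, mu, sigma, rho, D, NU))
        expect = 1.0 + rho * stats.norm.cdf(D, mu, sigma)
        assert abs((obs + missing) - expect) < 1e-9


class TestModLaplace:
    def test_peak_density(self):
        assert np.isclose(math.exp(mod_laplace_log_pdf(0.0, 1.0, 0.5)), 0.5)

    def test_zero_weight_side(self):
        assert mod_laplace_log_pdf(-0.1, 1.0, 1.0) == -math.inf
        assert np.isfinite(mod_laplace_log_pdf(0.1, 1.0, 1.0))

    @pytest.mark.parametrize("lam,phi", [(0.66, 0.3), (0.5, 0.5), (2.0, 0.9)])
    def test_normalises_to_one(self, lam, phi):
        val, _ = integrate.quad(
            lambda x: math.exp(mod_laplace_log_pdf(x, lam, phi)), -60, 60, limit=200
        )
        assert abs(val - 1.0) < 1e-8

    def test_matches_reference(self):
        for x in (-2.3, -0.1, 0.0, 0.4, 5.0):
            assert np.isclose(
                mod_laplace_log_pdf(x, 0.66, 0.3), ref_mod_laplace_logpdf(x, 0.66, 0.3)
            )


class TestGlobalLayer:
    def test_normal_peak_terms(self):
        n = 4
        local = LocalParams(
            mu=np.full(n, GLOBALS.mu_g), delta=np.zeros(n),
            kappa=np.full(n, GLOBALS.mu_kappa), tau=np.zeros(n),
        )
        val = global_layer_log_lik(local, GLOBALS)
        expect = n * (
            stats.norm.logpdf(0.0, 0.0, GLOBALS.sigma_g)
            + ref_mod_laplace_logpdf(0.0, 0.5, 0.5)
            + stats.norm.logpdf(0.0, 0.0, GLOBALS.sigma_kappa)
            + stats.norm.logpdf(0.0, 0.0, GLOBALS.sigma_tau)
        )
        assert np.isclose(val, expect)

    def test_kappa_symmetry(self):
        base = dict(mu=np.array([-5.0]), delta=np.array([0.3]), tau=np.array([0.1]))
        up = global_layer_log_lik(LocalParams(kappa=np.array([1.0 + 0.7]), **base), GLOBALS)
        dn = global_layer_log_lik(LocalParams(kappa=np.array([1.0 - 0.7]), **base), GLOBALS)
        assert np.isclose(up, dn)

    def test_componentwise_oracle(self):
        rng = np.random.default_rng(5)
        local = LocalParams(
            mu=rng.normal(-5, 1, 6), delta=rng.normal(0, 2, 6),
            kappa=rng.normal(1, 1, 6), tau=rng.normal(0, 2, 6),
        )
        expect = sum(
            stats.norm.logpdf(local.mu[s], -5.0, 1.0)
            + ref_mod_laplace_logpdf(local.delta[s], 0.5, 0.5)
            + stats.norm.logpdf(local.kappa[s], 1.0, 1.0)
            + stats.norm.logpdf(local.tau[s], 0.0, 2.0)
            for s in range(6)
        )
        assert np.isclose(global_layer_log_lik(local, GLOBALS), expect, atol=1e-10)


class TestGlobalPrior:
    @pytest.mark.parametrize(
        "kw", [dict(phi_delta=1.0), dict(phi_delta=0.0), dict(psi=2.5), dict(psi=0.0005)]
    )
    def test_out_of_support(self, kw):
        g = GLOBALS.replace(**kw)
        assert global_log_prior(g) == -math.inf

    def test_componentwise_oracle(self):
        expect = (
            stats.norm.logpdf(-5.0, -3.0, 5.0)
            + stats.invgamma.logpdf(1.0, 0.001, scale=0.001)
            + stats.uniform.logpdf(0.7, 0.001, 1.999)
            + stats.expon.logpdf(0.5)
            + stats.beta.logpdf(0.5, 2, 2)
            + stats.norm.logpdf(1.0, 0.0, 3.0)
            + stats.invgamma.logpdf(1.0, 0.001, scale=0.001)
            + stats.norm.logpdf(0.0, 0.0, 3.0)
            + stats.invgamma.logpdf(4.0, 0.001, scale=0.001)
        )
        assert np.isclose(global_log_prior(GLOBALS), expect, atol=1e-10)


class TestJointPosterior:
    def _fixture(self):
        from gelbayes import simulate, preset

        ds = simulate(preset("sim1", S=5, n_control=2, n_case=2), seed=9)
        rng = np.random.default_rng(4)
        local = LocalParams(
            mu=rng.normal(-5, 1, 5), delta=rng.normal(0, 1, 5),
            kappa=rng.normal(1, 1, 5), tau=rng.normal(0, 1, 5),
        )
        return ds.gel_matrix, local

    def test_matches_independent_scalar_reference(self):
        gm, local = self._fixture()
        got = joint_log_posterior(gm, local, GLOBALS)
        ref = ref_joint_log_posterior(gm, local, GLOBALS, D, NU)
        assert abs(got - ref) < 1e-10

    def test_deterministic(self):
        gm, local = self._fixture()
        assert joint_log_posterior(gm, local, GLOBALS) == joint_log_posterior(gm, local, GLOBALS)

    def test_out_of_support_state_is_minus_inf(self):
        gm, local = self._fixture()
        assert joint_log_posterior(gm, local, GLOBALS.replace(psi=3.0)) == -math.inf


def test_vectorised_and_scalar_spot_loglik_agree(tiny_gel_matrix):
    gm = tiny_gel_matrix
    rng = np.random.default_rng(2)
    local = LocalParams(
        mu=rng.normal(-5, 1, 3), delta=rng.normal(0, 1, 3),
        kappa=rng.normal(0, 1, 3), tau=rng.normal(0, 1, 3),
    )
    vec = local_log_lik_all(gm, local, 0.7)
    for s in range(3):
        scal = spot_log_lik(
            gm.values[s], gm.missing_mask[s], gm.is_case,
            local.mu[s], local.delta[s], local.kappa[s], local.tau[s],
            0.7, gm.constants,
        )
        assert abs(vec[s] - scal) < 1e-10


def test_label_swap_invariance_when_no_effects(tiny_gel_matrix):
    """With delta = tau = 0, exchanging group labels leaves the likelihood unchanged."""
    gm = tiny_gel_matrix
    local = LocalParams(
        mu=np.array([-4.5, -6.0, -2.2]), delta=np.zeros(3),
        kappa=np.array([0.5, -0.2, 1.0]), tau=np.zeros(3),
    )
    base = local_log_lik_all(gm, local, 0.7)
    from dataclasses import replace

    swapped = replace(gm, groups=["case" if g == "control" else "control" for g in gm.groups])
    assert np.allclose(local_log_lik_all(swapped, local, 0.7), base)
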