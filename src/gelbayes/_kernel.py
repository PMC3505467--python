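"""Jit-compiled iteration kernel for the block-updating MH sampler.

The Python layer (:mod:`gelbayes.mcmc`) owns initialisation, the adaptive
tuning schedule and trace assembly; this module executes batches of
iterations over a flat state representation.  All caches are per-spot
sufficient-statistic quantities, so one iteration costs O(S).

Layout of the flat global-state vector ``g`` (primed scale + expansion
multipliers; natural scale is ``mu = alpha * mu'``, ``var = alpha^2 * var'``):

====  =================
idx   parameter
====  =================
0     mu_g'
1     sigma_g^2'
2     alpha_mu
3     psi
4     lambda_delta
5     phi_delta
6     mu_kappa'
7     sigma_kappa^2'
8     alpha_kappa
9     mu_tau'
10    sigma_tau^2'
11    alpha_tau
====  =================

Block indices for proposal sds and acceptance counters:
0 mu_sigma_g, 1 alpha_mu, 2 lambda_phi, 3 psi, 4 mu_sigma_kappa,
5 alpha_kappa, 6 mu_sigma_tau, 7 alpha_tau, 8 local_mu_delta,
9 local_kappa_tau.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT_2PI = math.sqrt(2.0 * math.pi)
_SQRT1_2 = math.sqrt(0.5)
_TINY = 1e-300
_MASS_EPS = 1e-14

_IG_SHAPE = 0.001
_IG_RATE = 0.001
# log Gamma(0.001) computed once at import (scipy-free here: math.lgamma)
_IG_CONST = _IG_SHAPE * math.log(_IG_RATE) - math.lgamma(_IG_SHAPE)
_PSI_LOGWIDTH = math.log(2.0 - 0.001)


@njit(cache=True)
def _phi(x):
    # erfc-based: accurate deep into the lower tail
    return 0.5 * math.erfc(-x * _SQRT1_2)


@njit(cache=True)
def _trunc_mass(a, b):
    """Phi(b) - Phi(a) evaluated on the tail that avoids cancellation."""
    if a > 0.0:
        m = 0.5 * (math.erfc(a * _SQRT1_2) - math.erfc(b * _SQRT1_2))
    elif b < 0.0:
        m = 0.5 * (math.erfc(-b * _SQRT1_2) - math.erfc(-a * _SQRT1_2))
    else:
        m = _phi(b) - _phi(a)
    return m if m > _TINY else _TINY


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF: Acklam's rational approximation plus one
    Halley refinement against the erf-based CDF (near machine precision)."""
    if p < 1e-300:
        p = 1e-300
    if p > 1.0 - 1e-16:
        p = 1.0 - 1e-16
    if p < 0.02425:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
              + 4.374664141464968e+00) * q + 2.938163982698783e+00) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif p <= 0.97575:
        q = p - 0.5
        r = q * q
        x = (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
              - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / (
            ((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
               - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
             - 1.328068155288572e+01) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                 - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
               + 4.374664141464968e+00) * q + 2.938163982698783e+00) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    # Halley refinement
    e = _phi(x) - p
    u = e * _SQRT_2PI * math.exp(0.5 * x * x)
    return x - u / (1.0 + 0.5 * x * u)


@njit(cache=True)
def _truncnorm_prop(rng, current, sd, lower, upper):
    """Truncated-normal draw; returns (candidate, log Hastings correction)."""
    a = _phi((lower - current) / sd) if lower > -1e308 else 0.0
    b = _phi((upper - current) / sd) if upper < 1e308 else 1.0
    mass_cur = b - a
    if mass_cur < _MASS_EPS:
        return current, 0.0
    u = rng.uniform(0.0, 1.0)
    cand = current + sd * _ndtri(a + u * mass_cur)
    if cand < lower:
        cand = lower
    if cand > upper:
        cand = upper
    a2 = _phi((lower - cand) / sd) if lower > -1e308 else 0.0
    b2 = _phi((upper - cand) / sd) if upper < 1e308 else 1.0
    mass_cand = b2 - a2
    if mass_cand < _MASS_EPS:
        mass_cand = _MASS_EPS
    return cand, math.log(mass_cur) - math.log(mass_cand)


@njit(cache=True)
def _fast_prior(mu_g, var_g, psi, lam, phi, mu_k, var_k, mu_t, var_t):
    if var_g <= 0.0 or var_k <= 0.0 or var_t <= 0.0 or lam <= 0.0:
        return -math.inf
    if phi <= 0.0 or phi >= 1.0 or psi < 0.001 or psi > 2.0:
        return -math.inf
    z = (mu_g + 3.0) / 5.0
    lp = -0.5 * z * z - math.log(5.0) - _LOG_SQRT_2PI
    lp += _IG_CONST - (_IG_SHAPE + 1.0) * math.log(var_g) - _IG_RATE / var_g
    lp += -_PSI_LOGWIDTH
    lp += -lam
    lp += math.log(6.0) + math.log(phi) + math.log(1.0 - phi)
    z = mu_k / 3.0
    lp += -0.5 * z * z - math.log(3.0) - _LOG_SQRT_2PI
    lp += _IG_CONST - (_IG_SHAPE + 1.0) * math.log(var_k) - _IG_RATE / var_k
    z = mu_t / 3.0
    lp += -0.5 * z * z - math.log(3.0) - _LOG_SQRT_2PI
    lp += _IG_CONST - (_IG_SHAPE + 1.0) * math.log(var_t) - _IG_RATE / var_t
    return lp


@njit(cache=True)
def _spot_parts(sv, sv2, n_obs, n_miss, mu, rho, sigma, d, nu):
    """One spot-group likelihood with its (mu, sigma)-geometry parts."""
    phid = _phi((d - mu) / sigma)
    loglam = math.log(_trunc_mass((d - mu) / sigma, (nu - mu) / sigma))
    quad = -0.5 * (sv2 - 2.0 * mu * sv + mu * mu * n_obs) / (sigma * sigma)
    ll = quad
    if n_obs > 0.0:
        r = rho if rho > _TINY else _TINY
        ll += n_obs * (math.log(r) - math.log(sigma) - _LOG_SQRT_2PI - loglam)
    if n_miss > 0.0:
        mix = (1.0 - rho) + rho * phid
        if mix < _TINY:
            mix = _TINY
        ll += n_miss * math.log(mix)
    return ll, quad, phid, loglam


@njit(cache=True)
def _assemble(n_obs, n_miss, quad, phid, loglam, rho, sigma):
    """Likelihood from cached geometry with a new expression probability."""
    ll = quad
    if n_obs > 0.0:
        r = rho if rho > _TINY else _TINY
        ll += n_obs * (math.log(r) - math.log(sigma) - _LOG_SQRT_2PI - loglam)
    if n_miss > 0.0:
        mix = (1.0 - rho) + rho * phid
        if mix < _TINY:
            mix = _TINY
        ll += n_miss * math.log(mix)
    return ll


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _norm_logpdf(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI


@njit(cache=True)
def _laplace_logpdf(delta, lam, phi):
    if delta < 0.0:
        return math.log(1.0 - phi) + math.log(lam) + lam * delta
    return math.log(phi) + math.log(lam) - lam * delta


@njit(cache=True)
def _eval_sigma_candidate(mu_g_c, sig_g_c, sig_c,
                          sv0, sv20, nobs0, nmiss0, sv1, sv21, nobs1, nmiss1,
                          mu, delta, rho0, rho1, d, nu,
                          c_ll, c_glmu, c_q0, c_p0, c_l0, c_q1, c_p1, c_l1):
    """Candidate full local likelihood + mu_s global terms for new scales."""
    S = mu.shape[0]
    ll_sum = 0.0
    glmu_sum = 0.0
    for s in range(S):
        ll0, q0, p0, l0 = _spot_parts(sv0[s], sv20[s], nobs0[s], nmiss0[s],
                                      mu[s], rho0[s], sig_c, d, nu)
        ll1, q1, p1, l1 = _spot_parts(sv1[s], sv21[s], nobs1[s], nmiss1[s],
                                      mu[s] + delta[s], rho1[s], sig_c, d, nu)
        c_ll[s] = ll0 + ll1
        c_q0[s], c_p0[s], c_l0[s] = q0, p0, l0
        c_q1[s], c_p1[s], c_l1[s] = q1, p1, l1
        g = _norm_logpdf(mu[s], mu_g_c, sig_g_c)
        c_glmu[s] = g
        ll_sum += c_ll[s]
        glmu_sum += g
    return ll_sum, glmu_sum


@njit(cache=True)
def run_iters(rng, it0, n_iter, expansion,
              sv0, sv20, nobs0, nmiss0, sv1, sv21, nobs1, nmiss1,
              mu, delta, kappa, tau,
              g,
              ll, gl_mu, gl_delta, gl_kappa, gl_tau, rho0, rho1,
              q0, p0, l0, q1, p1, l1,
              sums, sds, acc,
              d, nu,
              thin, rec, rec_states, row_ptr):
    """Advance the chain ``n_iter`` iterations in place; record thinned rows.

    ``sums`` carries [ll_sum, gl_mu_sum, gl_delta_sum, gl_kappa_sum,
    gl_tau_sum, log_prior].  ``acc`` accumulates (accepts, attempts) per
    block.  Returns the updated record-row pointer.
    """
    S = mu.shape[0]
    c_ll = np.empty(S)
    c_glmu = np.empty(S)
    c_q0 = np.empty(S)
    c_p0 = np.empty(S)
    c_l0 = np.empty(S)
    c_q1 = np.empty(S)
    c_p1 = np.empty(S)
    c_l1 = np.empty(S)

    for k in range(n_iter):
        it = it0 + k + 1

        # natural-scale parameters
        mu_g = g[2] * g[0]
        var_g = g[2] * g[2] * g[1]
        mu_k = g[8] * g[6]
        var_k = g[8] * g[8] * g[7]
        mu_t = g[11] * g[9]
        var_t = g[11] * g[11] * g[10]

        # ---- block 0: (mu_g', sigma_g2') -------------------------------
        # proposals live on the primed scale and are unconstrained (beyond
        # variance positivity); the support bounds mu_g in [d, nu] and
        # sigma >= 0.01 are enforced on the NATURAL scale by rejection, so
        # the expansion fiber stays free and the natural posterior is the
        # same with and without expansion
        # proposal scales divided by alpha (alpha^2 for variances) so the
        # natural-scale step size does not depend on the current expansion
        # multiplier
        sd = sds[0]
        mu_p_c = g[0] + (sd / g[2]) * rng.standard_normal()
        h1 = 0.0
        var_p_c, h2 = _truncnorm_prop(rng, g[1], sd / (g[2] * g[2]), 1e-12, math.inf)
        mu_g_c = g[2] * mu_p_c
        var_g_c = g[2] * g[2] * var_p_c
        acc[0, 1] += 1
        u = rng.uniform(0.0, 1.0)
        if d <= mu_g_c <= nu and var_g_c >= 1e-4:
            pr_c = _fast_prior(mu_g_c, var_g_c, g[3], g[4], g[5], mu_k, var_k, mu_t, var_t)
        else:
            pr_c = -math.inf
        if pr_c > -math.inf:
            sig_g_c = math.sqrt(var_g_c)
            sig_c = g[3] * sig_g_c
            ll_sum_c, glmu_sum_c = _eval_sigma_candidate(
                mu_g_c, sig_g_c, sig_c, sv0, sv20, nobs0, nmiss0,
                sv1, sv21, nobs1, nmiss1, mu, delta, rho0, rho1, d, nu,
                c_ll, c_glmu, c_q0, c_p0, c_l0, c_q1, c_p1, c_l1)
            dlp = (ll_sum_c - sums[0]) + (glmu_sum_c - sums[1]) + (pr_c - sums[5])
            if math.log(u) < dlp + h1 + h2:
                g[0] = mu_p_c
                g[1] = var_p_c
                mu_g, var_g = mu_g_c, var_g_c
                for s in range(S):
                    ll[s] = c_ll[s]
                    gl_mu[s] = c_glmu[s]
                    q0[s], p0[s], l0[s] = c_q0[s], c_p0[s], c_l0[s]
                    q1[s], p1[s], l1[s] = c_q1[s], c_p1[s], c_l1[s]
                sums[0], sums[1], sums[5] = ll_sum_c, glmu_sum_c, pr_c
                acc[0, 0] += 1

        # ---- block 1: alpha_mu ----------------------------------------
        if expansion:
            sd = sds[1]
            a_c, h1 = _truncnorm_prop(rng, g[2], sd, 0.01, math.inf)
            acc[1, 1] += 1
            u = rng.uniform(0.0, 1.0)
            if a_c <= 10.0:
                mu_g_c = a_c * g[0]
                var_g_c = a_c * a_c * g[1]
                if d <= mu_g_c <= nu and var_g_c >= 1e-4:
                    pr_c = _fast_prior(mu_g_c, var_g_c, g[3], g[4], g[5],
                                       mu_k, var_k, mu_t, var_t)
                else:
                    pr_c = -math.inf
                if pr_c > -math.inf:
                    sig_g_c = math.sqrt(var_g_c)
                    sig_c = g[3] * sig_g_c
                    ll_sum_c, glmu_sum_c = _eval_sigma_candidate(
                        mu_g_c, sig_g_c, sig_c, sv0, sv20, nobs0, nmiss0,
                        sv1, sv21, nobs1, nmiss1, mu, delta, rho0, rho1, d, nu,
                        c_ll, c_glmu, c_q0, c_p0, c_l0, c_q1, c_p1, c_l1)
                    dlp = (ll_sum_c - sums[0]) + (glmu_sum_c - sums[1]) + (pr_c - sums[5])
                    # expanded-target Jacobian |d(natural)/d(primed)| = alpha^3
                    dlp += 3.0 * (math.log(a_c) - math.log(g[2]))
                    if math.log(u) < dlp + h1:
                        g[2] = a_c
                        mu_g, var_g = mu_g_c, var_g_c
                        for s in range(S):
                            ll[s] = c_ll[s]
                            gl_mu[s] = c_glmu[s]
                            q0[s], p0[s], l0[s] = c_q0[s], c_p0[s], c_l0[s]
                            q1[s], p1[s], l1[s] = c_q1[s], c_p1[s], c_l1[s]
                        sums[0], sums[1], sums[5] = ll_sum_c, glmu_sum_c, pr_c
                        acc[1, 0] += 1

        # ---- block 2: (lambda_delta, phi_delta) ------------------------
        sd = sds[2]
        lam_c, h1 = _truncnorm_prop(rng, g[4], sd, 0.01, math.inf)
        logit = math.log(g[5] / (1.0 - g[5]))
        phi_c = _expit(logit + sd * rng.standard_normal())
        if phi_c < 1e-12:
            phi_c = 1e-12
        if phi_c > 1.0 - 1e-12:
            phi_c = 1.0 - 1e-12
        h2 = math.log(phi_c * (1.0 - phi_c)) - math.log(g[5] * (1.0 - g[5]))
        pr_c = _fast_prior(mu_g, var_g, g[3], lam_c, phi_c, mu_k, var_k, mu_t, var_t)
        acc[2, 1] += 1
        u = rng.uniform(0.0, 1.0)
        if pr_c > -math.inf:
            gld_sum_c = 0.0
            for s in range(S):
                c_ll[s] = _laplace_logpdf(delta[s], lam_c, phi_c)
                gld_sum_c += c_ll[s]
            dlp = (gld_sum_c - sums[2]) + (pr_c - sums[5])
            if math.log(u) < dlp + h1 + h2:
                g[4], g[5] = lam_c, phi_c
                for s in range(S):
                    gl_delta[s] = c_ll[s]
                sums[2], sums[5] = gld_sum_c, pr_c
                acc[2, 0] += 1

        # ---- block 3: psi ----------------------------------------------
        sd = sds[3]
        psi_c, h1 = _truncnorm_prop(rng, g[3], sd, 0.001, 2.0)
        pr_c = _fast_prior(mu_g, var_g, psi_c, g[4], g[5], mu_k, var_k, mu_t, var_t)
        acc[3, 1] += 1
        u = rng.uniform(0.0, 1.0)
        if pr_c > -math.inf:
            sig_g_cur = math.sqrt(var_g)
            sig_c = psi_c * sig_g_cur
            ll_sum_c, glmu_sum_c = _eval_sigma_candidate(
                mu_g, sig_g_cur, sig_c, sv0, sv20, nobs0, nmiss0,
                sv1, sv21, nobs1, nmiss1, mu, delta, rho0, rho1, d, nu,
                c_ll, c_glmu, c_q0, c_p0, c_l0, c_q1, c_p1, c_l1)
            dlp = (ll_sum_c - sums[0]) + (glmu_sum_c - sums[1]) + (pr_c - sums[5])
            if math.log(u) < dlp + h1:
                g[3] = psi_c
                for s in range(S):
                    ll[s] = c_ll[s]
                    gl_mu[s] = c_glmu[s]
                    q0[s], p0[s], l0[s] = c_q0[s], c_p0[s], c_l0[s]
                    q1[s], p1[s], l1[s] = c_q1[s], c_p1[s], c_l1[s]
                sums[0], sums[1], sums[5] = ll_sum_c, glmu_sum_c, pr_c
                acc[3, 0] += 1

        # ---- blocks 4-7: kappa- and tau-layer means/variances + alphas --
        for layer in range(2):
            if layer == 0:
                i_mu, i_var, i_al = 6, 7, 8
                b_ms, b_al = 4, 5
            else:
                i_mu, i_var, i_al = 9, 10, 11
                b_ms, b_al = 6, 7

            # (mu', var') block; proposal scales divided by alpha / alpha^2
            sd = sds[b_ms]
            al = g[i_al]
            mu_p_c = g[i_mu] + (sd / al) * rng.standard_normal()
            var_p_c, h1 = _truncnorm_prop(rng, g[i_var], sd / (al * al), 1e-12, math.inf)
            mu_n_c = al * mu_p_c
            var_n_c = al * al * var_p_c
            if var_n_c < 1e-4:
                mu_n_c = math.nan  # force support rejection below
            if layer == 0:
                pr_c = _fast_prior(mu_g, var_g, g[3], g[4], g[5], mu_n_c, var_n_c, mu_t, var_t)
            else:
                pr_c = _fast_prior(mu_g, var_g, g[3], g[4], g[5], mu_k, var_k, mu_n_c, var_n_c)
            acc[b_ms, 1] += 1
            u = rng.uniform(0.0, 1.0)
            if pr_c > -math.inf:
                sig_n_c = math.sqrt(var_n_c)
                gsum_c = 0.0
                if layer == 0:
                    for s in range(S):
                        c_ll[s] = _norm_logpdf(kappa[s], mu_n_c, sig_n_c)
                        gsum_c += c_ll[s]
                    dlp = (gsum_c - sums[3]) + (pr_c - sums[5])
                else:
                    for s in range(S):
                        c_ll[s] = _norm_logpdf(tau[s], mu_n_c, sig_n_c)
                        gsum_c += c_ll[s]
                    dlp = (gsum_c - sums[4]) + (pr_c - sums[5])
                if math.log(u) < dlp + h1:
                    g[i_mu], g[i_var] = mu_p_c, var_p_c
                    if layer == 0:
                        mu_k, var_k = mu_n_c, var_n_c
                        for s in range(S):
                            gl_kappa[s] = c_ll[s]
                        sums[3] = gsum_c
                    else:
                        mu_t, var_t = mu_n_c, var_n_c
                        for s in range(S):
                            gl_tau[s] = c_ll[s]
                        sums[4] = gsum_c
                    sums[5] = pr_c
                    acc[b_ms, 0] += 1

            # alpha block
            if expansion:
                sd = sds[b_al]
                a_c, h1 = _truncnorm_prop(rng, g[i_al], sd, 0.01, math.inf)
                acc[b_al, 1] += 1
                u = rng.uniform(0.0, 1.0)
                if a_c <= 10.0:
                    mu_n_c = a_c * g[i_mu]
                    var_n_c = a_c * a_c * g[i_var]
                    if var_n_c < 1e-4:
                        mu_n_c = math.nan  # force support rejection below
                    if layer == 0:
                        pr_c = _fast_prior(mu_g, var_g, g[3], g[4], g[5],
                                           mu_n_c, var_n_c, mu_t, var_t)
                    else:
                        pr_c = _fast_prior(mu_g, var_g, g[3], g[4], g[5],
                                           mu_k, var_k, mu_n_c, var_n_c)
                    if pr_c > -math.inf:
                        sig_n_c = math.sqrt(var_n_c)
                        gsum_c = 0.0
                        if layer == 0:
                            for s in range(S):
                                c_ll[s] = _norm_logpdf(kappa[s], mu_n_c, sig_n_c)
                                gsum_c += c_ll[s]
                            dlp = (gsum_c - sums[3]) + (pr_c - sums[5])
                        else:
                            for s in range(S):
                                c_ll[s] = _norm_logpdf(tau[s], mu_n_c, sig_n_c)
                                gsum_c += c_ll[s]
                            dlp = (gsum_c - sums[4]) + (pr_c - sums[5])
                        # expanded-target Jacobian alpha^3
                        dlp += 3.0 * (math.log(a_c) - math.log(g[i_al]))
                        if math.log(u) < dlp + h1:
                            g[i_al] = a_c
                            if layer == 0:
                                mu_k, var_k = mu_n_c, var_n_c
                                for s in range(S):
                                    gl_kappa[s] = c_ll[s]
                                sums[3] = gsum_c
                            else:
                                mu_t, var_t = mu_n_c, var_n_c
                                for s in range(S):
                                    gl_tau[s] = c_ll[s]
                                sums[4] = gsum_c
                            sums[5] = pr_c
                            acc[b_al, 0] += 1

        # ---- block 8: local (mu_s, delta_s), all spots -----------------
        sig_g_cur = math.sqrt(var_g)
        sig = g[3] * sig_g_cur
        sd = sds[8]
        for s in range(S):
            mu_c = mu[s] + sd * rng.standard_normal()
            de_c = delta[s] + sd * rng.standard_normal()
            ll0, nq0, np0, nl0 = _spot_parts(sv0[s], sv20[s], nobs0[s], nmiss0[s],
                                             mu_c, rho0[s], sig, d, nu)
            ll1, nq1, np1, nl1 = _spot_parts(sv1[s], sv21[s], nobs1[s], nmiss1[s],
                                             mu_c + de_c, rho1[s], sig, d, nu)
            ll_c = ll0 + ll1
            glmu_c = _norm_logpdf(mu_c, mu_g, sig_g_cur)
            gld_c = _laplace_logpdf(de_c, g[4], g[5])
            dlp = (ll_c - ll[s]) + (glmu_c - gl_mu[s]) + (gld_c - gl_delta[s])
            acc[8, 1] += 1
            if math.log(rng.uniform(0.0, 1.0)) < dlp:
                sums[0] += ll_c - ll[s]
                sums[1] += glmu_c - gl_mu[s]
                sums[2] += gld_c - gl_delta[s]
                mu[s], delta[s] = mu_c, de_c
                ll[s], gl_mu[s], gl_delta[s] = ll_c, glmu_c, gld_c
                q0[s], p0[s], l0[s] = nq0, np0, nl0
                q1[s], p1[s], l1[s] = nq1, np1, nl1
                acc[8, 0] += 1

        # ---- block 9: local (kappa_s, tau_s), all spots ----------------
        sd = sds[9]
        sig_k = math.sqrt(var_k)
        sig_t = math.sqrt(var_t)
        for s in range(S):
            ka_c = kappa[s] + sd * rng.standard_normal()
            ta_c = tau[s] + sd * rng.standard_normal()
            r0_c = _expit(ka_c)
            r1_c = _expit(ka_c + ta_c)
            ll_c = (_assemble(nobs0[s], nmiss0[s], q0[s], p0[s], l0[s], r0_c, sig)
                    + _assemble(nobs1[s], nmiss1[s], q1[s], p1[s], l1[s], r1_c, sig))
            glk_c = _norm_logpdf(ka_c, mu_k, sig_k)
            glt_c = _norm_logpdf(ta_c, mu_t, sig_t)
            dlp = (ll_c - ll[s]) + (glk_c - gl_kappa[s]) + (glt_c - gl_tau[s])
            acc[9, 1] += 1
            if math.log(rng.uniform(0.0, 1.0)) < dlp:
                sums[0] += ll_c - ll[s]
                sums[3] += glk_c - gl_kappa[s]
                sums[4] += glt_c - gl_tau[s]
                kappa[s], tau[s] = ka_c, ta_c
                rho0[s], rho1[s] = r0_c, r1_c
                ll[s], gl_kappa[s], gl_tau[s] = ll_c, glk_c, glt_c
                acc[9, 0] += 1

        # ---- record -----------------------------------------------------
        if it % thin == 0:
            j = row_ptr
            rec[j, 0] = mu_g
            rec[j, 1] = math.sqrt(var_g)
            rec[j, 2] = g[3]
            rec[j, 3] = g[4]
            rec[j, 4] = g[5]
            rec[j, 5] = mu_k
            rec[j, 6] = math.sqrt(var_k)
            rec[j, 7] = mu_t
            rec[j, 8] = math.sqrt(var_t)
            rec[j, 9] = g[2]
            rec[j, 10] = g[8]
            rec[j, 11] = g[11]
            for s in range(S):
                base = 12 + 4 * s
                rec[j, base] = mu[s]
                rec[j, base + 1] = delta[s]
                rec[j, base + 2] = kappa[s]
                rec[j, base + 3] = tau[s]
            rec[j, 12 + 4 * S] = (sums[0] + sums[1] + sums[2] + sums[3]
                                  + sums[4] + sums[5])
            rec_states[j] = it
            row_ptr += 1

    return row_ptr
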