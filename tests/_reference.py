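"""Independent scalar reference implementations used as test oracles.

Everything here is written plainly (no vectorisation, scipy.stats-based
densities, brute-force scans) and deliberately shares no code with the
package's computational paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ref_truncnorm_mass(mu, sigma, d, nu):
    """Normal mass on [d, nu] via the distribution object."""
    dist = stats.norm(mu, sigma)
    return dist.cdf(nu) - dist.cdf(d)


def ref_obs_loglik(c, mu, sigma, rho, d, nu):
    """One observation's censored-mixture log density, straight from the
    definition: missing -> (1 - rho) + rho * Phi((d - mu)/sigma); observed
    -> rho * truncated-normal density on [d, nu]."""
    if c is None or (isinstance(c, float) and math.isnan(c)):
        return math.log((1.0 - rho) + rho * stats.norm.cdf(d, mu, sigma))
    lam = ref_truncnorm_mass(mu, sigma, d, nu)
    return math.log(rho) + stats.norm.logpdf(c, mu, sigma) - math.log(lam)


def ref_mod_laplace_logpdf(x, lam, phi):
    if x < 0:
        return math.log(1.0 - phi) + math.log(lam) + lam * x
    return math.log(phi) + math.log(lam) - lam * x


def ref_joint_log_posterior(gm, local, g, d, nu):
    """Fully scalar log posterior: loops over spots and gels, scipy densities."""
    sigma_s = g.psi * g.sigma_g
    total = 0.0
    for s in range(gm.n_spots):
        p0 = 1.0 / (1.0 + math.exp(-local.kappa[s]))
        p1 = 1.0 / (1.0 + math.exp(-(local.kappa[s] + local.tau[s])))
        for j in range(gm.n_gels):
            case = gm.groups[j] == "case"
            mu_x = local.mu[s] + (local.delta[s] if case else 0.0)
            rho = p1 if case else p0
            c = None if gm.missing_mask[s, j] else float(gm.values[s, j])
            total += ref_obs_loglik(c, mu_x, sigma_s, rho, d, nu)
        # global layer
        total += stats.norm.logpdf(local.mu[s], g.mu_g, g.sigma_g)
        total += ref_mod_laplace_logpdf(local.delta[s], g.lambda_delta, g.phi_delta)
        total += stats.norm.logpdf(local.kappa[s], g.mu_kappa, g.sigma_kappa)
        total += stats.norm.logpdf(local.tau[s], g.mu_tau, g.sigma_tau)
    # priors
    total += stats.norm.logpdf(g.mu_g, -3.0, 5.0)
    total += stats.invgamma.logpdf(g.sigma_g**2, 0.001, scale=0.001)
    total += stats.uniform.logpdf(g.psi, 0.001, 2.0 - 0.001)
    total += stats.expon.logpdf(g.lambda_delta)
    total += stats.beta.logpdf(g.phi_delta, 2.0, 2.0)
    total += stats.norm.logpdf(g.mu_kappa, 0.0, 3.0)
    total += stats.invgamma.logpdf(g.sigma_kappa**2, 0.001, scale=0.001)
    total += stats.norm.logpdf(g.mu_tau, 0.0, 3.0)
    total += stats.invgamma.logpdf(g.sigma_tau**2, 0.001, scale=0.001)
    return total


def ref_hpd(samples, mass=0.95):
    """Exhaustive scan over every window of ceil(mass*n) order statistics."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    w = int(math.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    best = None
    for i in range(n - w + 1):
        width = x[i + w - 1] - x[i]
        if best is None or width < best[0] - 1e-15:
            best = (width, x[i], x[i + w - 1])
    return float(best[1]), float(best[2])
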