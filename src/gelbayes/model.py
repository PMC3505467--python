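"""Two-layer censored-mixture model for 2D PAGE spot intensities.

Local layer
-----------
Each spot ``s`` has four parameters: the control-group mean intensity
``mu_s``, the case-minus-control difference ``delta_s`` (case mean is
``mu_s + delta_s``), and logit-scale expression propensities ``kappa_s``
(control) and ``tau_s`` (case-minus-control difference), giving expression
probabilities ``p0 = logit^-1(kappa_s)`` and ``p1 = logit^-1(kappa_s +
tau_s)``.  An observed intensity ``c`` in ``[d, nu]`` contributes a
truncated-normal density scaled by the expression probability; a missing
cell contributes the mixture mass ``(1 - rho) + rho * Phi((d - mu)/sigma)``
of non-expression plus expression censored below the detection limit ``d``.
All spots share one standard deviation ``sigma_s = psi * sigma_g``.

Global layer
------------
Spot means are Normal(mu_g, sigma_g); intensity differences delta_s follow
an asymmetric ("modified") Laplace law with rate ``lambda_delta`` and
up-regulated proportion ``phi_delta``; kappa_s and tau_s are Normal with
means mu_kappa, mu_tau and standard deviations sigma_kappa, sigma_tau.

Everything here is evaluated in log space.  The scalar operations are the
reference API; the ``*_all`` functions are the vectorised forms the MCMC
engine uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc, gammaln, ndtr

from .gel_io import GelMatrix, ModelConstants

__all__ = [
    "LocalParams",
    "GlobalParams",
    "expression_prob",
    "truncnorm_mass",
    "spot_obs_log_lik",
    "spot_log_lik",
    "local_log_lik_all",
    "mod_laplace_log_pdf",
    "global_layer_log_lik",
    "global_log_prior",
    "joint_log_posterior",
    "LOG_FLOOR",
]

#: Substituted for -inf only at the Metropolis-Hastings comparison point.
LOG_FLOOR = -1e308

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
# smallest admissible probability mass before taking logs; keeps log-space
# arithmetic finite when a mean sits far outside [d, nu]
_TINY = 1e-300


@dataclass
class LocalParams:
    """Per-spot parameters, stored as aligned vectors over spots."""

    mu: np.ndarray
    delta: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        n = self.mu.size
        if not (self.delta.size == self.kappa.size == self.tau.size == n):
            raise ValueError("local parameter vectors must share one length")

    @property
    def n_spots(self) -> int:
        return self.mu.size

    def copy(self) -> "LocalParams":
        return LocalParams(self.mu.copy(), self.delta.copy(), self.kappa.copy(), self.tau.copy())


@dataclass(frozen=True)
class GlobalParams:
    """The nine global-layer parameters (natural scale)."""

    mu_g: float
    sigma_g: float
    psi: float
    lambda_delta: float
    phi_delta: float
    mu_kappa: float
    sigma_kappa: float
    mu_tau: float
    sigma_tau: float

    @property
    def sigma_s(self) -> float:
        """Common spot standard deviation, sigma_s = psi * sigma_g."""
        return self.psi * self.sigma_g

    def in_support(self) -> bool:
        return (
            self.sigma_g > 0
            and 0.001 <= self.psi <= 2.0
            and self.lambda_delta > 0
            and 0.0 < self.phi_delta < 1.0
            and self.sigma_kappa > 0
            and self.sigma_tau > 0
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_g": self.mu_g,
            "sigma_g": self.sigma_g,
            "psi": self.psi,
            "lambda_delta": self.lambda_delta,
            "phi_delta": self.phi_delta,
            "mu_kappa": self.mu_kappa,
            "sigma_kappa": self.sigma_kappa,
            "mu_tau": self.mu_tau,
            "sigma_tau": self.sigma_tau,
        }

    def replace(self, **kw: float) -> "GlobalParams":
        return replace(self, **kw)


def expression_prob(kappa, tau=None):
    """Inverse-logit expression probability p0 (or p1 when ``tau`` given).

    Numerically stable for large |kappa|; saturates smoothly at 0/1.
    """
    x = np.asarray(kappa, dtype=float)
    if tau is not None:
        x = x + np.asarray(tau, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out if out.ndim else float(out)


_SQRT1_2 = math.sqrt(0.5)


def truncnorm_mass(mu, sigma, d, nu):
    """Normal probability mass ``lambda`` on the detection window [d, nu].

    This is the normaliser of the truncated-normal intensity density.  The
    difference of CDFs is evaluated on whichever tail avoids catastrophic
    cancellation (via erfc when the window sits entirely in one tail) and is
    floored at a tiny positive value so downstream logs stay finite.
    """
    mu = np.asarray(mu, dtype=float)
    a = (d - mu) / sigma
    b = (nu - mu) / sigma
    upper = 0.5 * (erfc(a * _SQRT1_2) - erfc(b * _SQRT1_2))  # accurate for a > 0
    lower = 0.5 * (erfc(-b * _SQRT1_2) - erfc(-a * _SQRT1_2))  # accurate for b < 0
    mid = ndtr(b) - ndtr(a)
    mass = np.where(a > 0, upper, np.where(b < 0, lower, mid))
    mass = np.maximum(mass, _TINY)
    return mass if mass.ndim else float(mass)


def _normal_logpdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI


def spot_obs_log_lik(c, mu_x, sigma_s, rho_x, d, nu):
    """Log density/mass of one observation under the censored mixture.

    ``c`` is the observed log2 percent volume, or None/NaN for a missing
    ("NA") cell.  A missing cell mixes non-expression (mass ``1 - rho_x``)
    with expression censored below ``d``; an observed cell contributes
    ``rho_x`` times the normal density truncated to ``[d, nu]``.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if c is None or (isinstance(c, float) and math.isnan(c)):
        mass = (1.0 - rho_x) + rho_x * ndtr((d - mu_x) / sigma_s)
        return float(np.log(max(mass, _TINY)))
    c = float(c)
    if c > nu + 1e-12:
        raise ValueError(f"observed value {c} exceeds maximum expression value {nu}")
    if rho_x <= 0.0:
        return LOG_FLOOR
    lam = truncnorm_mass(mu_x, sigma_s, d, nu)
    return float(math.log(rho_x) + _normal_logpdf(c, mu_x, sigma_s) - math.log(lam))


def spot_log_lik(
    values_row: np.ndarray,
    missing_row: np.ndarray,
    is_case: np.ndarray,
    mu: float,
    delta: float,
    kappa: float,
    tau: float,
    sigma_s: float,
    constants: ModelConstants,
) -> float:
    """Log likelihood of one spot's row: controls use (mu, p0), cases (mu + delta, p1)."""
    p0 = expression_prob(kappa)
    p1 = expression_prob(kappa, tau)
    total = 0.0
    for j in range(len(is_case)):
        c = None if missing_row[j] else float(values_row[j])
        if is_case[j]:
            total += spot_obs_log_lik(c, mu + delta, sigma_s, p1, constants.d, constants.nu)
        else:
            total += spot_obs_log_lik(c, mu, sigma_s, p0, constants.d, constants.nu)
    return total


def local_log_lik_all(
    gm: GelMatrix,
    local: LocalParams,
    sigma_s: float,
    constants: ModelConstants | None = None,
) -> np.ndarray:
    """Vectorised per-spot local-layer log likelihood, one value per spot."""
    constants = constants or gm.constants
    d, nu = constants.d, constants.nu
    is_case = gm.is_case
    out = np.zeros(local.n_spots)
    for grp, sel in ((0, ~is_case), (1, is_case)):
        v = gm.values[:, sel]
        obs = ~gm.missing_mask[:, sel]
        mu_x = local.mu if grp == 0 else local.mu + local.delta
        rho = expression_prob(local.kappa) if grp == 0 else expression_prob(local.kappa, local.tau)
        n_obs = obs.sum(axis=1)
        n_miss = obs.shape[1] - n_obs
        z = np.where(obs, (np.nan_to_num(v) - mu_x[:, None]) / sigma_s, 0.0)
        quad = -0.5 * np.einsum("ij,ij->i", z, z)
        phi_d = ndtr((d - mu_x) / sigma_s)
        lam = truncnorm_mass(mu_x, sigma_s, d, nu)
        with np.errstate(divide="ignore"):
            obs_part = quad + n_obs * (np.log(np.maximum(rho, _TINY)) - math.log(sigma_s) - _LOG_SQRT_2PI - np.log(lam))
            miss_part = n_miss * np.log(np.maximum((1.0 - rho) + rho * phi_d, _TINY))
        out += np.where(n_obs > 0, obs_part, 0.0) + np.where(n_miss > 0, miss_part, 0.0)
        # an observed cell with rho == 0 is impossible: drive to the floor
        out = np.where((n_obs > 0) & (rho <= 0.0), LOG_FLOOR, out)
    return out


def mod_laplace_log_pdf(delta, lambda_delta: float, phi_delta: float):
    """Log pdf of the asymmetric (weighted) Laplace law for delta_s.

    Negative differences carry weight ``1 - phi_delta`` on an Exponential
    (rate ``lambda_delta``) decay; non-negative differences carry weight
    ``phi_delta``.  Each side integrates to its weight, so the density is
    normalised for any ``phi_delta`` in [0, 1].
    """
    if lambda_delta <= 0:
        raise ValueError("lambda_delta must be positive")
    if not 0.0 <= phi_delta <= 1.0:
        raise ValueError("phi_delta must lie in [0, 1]")
    delta = np.asarray(delta, dtype=float)
    log_lam = math.log(lambda_delta)
    with np.errstate(divide="ignore"):
        neg = math.log(1.0 - phi_delta) if phi_delta < 1.0 else -math.inf
        pos = math.log(phi_delta) if phi_delta > 0.0 else -math.inf
    out = np.where(
        delta < 0,
        neg + log_lam + lambda_delta * delta,
        pos + log_lam - lambda_delta * delta,
    )
    return out if out.ndim else float(out)


def global_layer_log_lik(local: LocalParams, g: GlobalParams) -> float:
    """Log of the global-layer product over spots.

    Sum over spots of the Normal(mu_g, sigma_g) term for mu_s, the modified
    Laplace term for delta_s, and the Normal terms for kappa_s and tau_s.
    """
    if not g.in_support():
        return -math.inf
    total = float(np.sum(_normal_logpdf(local.mu, g.mu_g, g.sigma_g)))
    total += float(np.sum(mod_laplace_log_pdf(local.delta, g.lambda_delta, g.phi_delta)))
    total += float(np.sum(_normal_logpdf(local.kappa, g.mu_kappa, g.sigma_kappa)))
    total += float(np.sum(_normal_logpdf(local.tau, g.mu_tau, g.sigma_tau)))
    return total


def _invgamma_logpdf(v: float, shape: float, rate: float) -> float:
    if v <= 0:
        return -math.inf
    return shape * math.log(rate) - gammaln(shape) - (shape + 1.0) * math.log(v) - rate / v


def global_log_prior(g: GlobalParams) -> float:
    """Log prior over the nine global parameters.

    mu_g ~ Normal(-3, 5); sigma_g^2, sigma_kappa^2, sigma_tau^2 ~
    InverseGamma(0.001, 0.001); psi ~ Uniform(0.001, 2); lambda_delta ~
    Exponential(1); phi_delta ~ Beta(2, 2); mu_kappa, mu_tau ~ Normal(0, 3).
    Returns -inf outside any support.
    """
    if not g.in_support():
        return -math.inf
    lp = float(_normal_logpdf(g.mu_g, -3.0, 5.0))
    lp += _invgamma_logpdf(g.sigma_g**2, 0.001, 0.001)
    lp += -math.log(2.0 - 0.001)  # Uniform(0.001, 2) on psi
    lp += -g.lambda_delta  # Exponential(1)
    lp += math.log(6.0) + math.log(g.phi_delta) + math.log(1.0 - g.phi_delta)  # Beta(2,2)
    lp += float(_normal_logpdf(g.mu_kappa, 0.0, 3.0))
    lp += _invgamma_logpdf(g.sigma_kappa**2, 0.001, 0.001)
    lp += float(_normal_logpdf(g.mu_tau, 0.0, 3.0))
    lp += _invgamma_logpdf(g.sigma_tau**2, 0.001, 0.001)
    return lp


def joint_log_posterior(
    gm: GelMatrix,
    local: LocalParams,
    g: GlobalParams,
    constants: ModelConstants | None = None,
) -> float:
    """Unnormalised log posterior: local layer + global layer + global prior."""
    prior = global_log_prior(g)
    if not math.isfinite(prior):
        return -math.inf
    glob = global_layer_log_lik(local, g)
    if not math.isfinite(glob):
        return -math.inf
    loc = float(np.sum(local_log_lik_all(gm, local, g.sigma_s, constants)))
    return loc + glob + prior
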