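"""Univariate maximum-likelihood baseline: per-spot likelihood ratio test.

Each spot is fit on its own with the same censored-mixture likelihood as
the hierarchical model but with a free per-spot standard deviation
``sigma_s`` (the hierarchical model instead shares ``psi * sigma_g`` across
spots — exactly the contrast the two methods are compared on).  The null
model constrains ``delta_s = tau_s = 0`` (no difference in mean intensity or
expression propensity); the test statistic ``2 (lnL_full - lnL_null)`` is
referred to a chi-square distribution with 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .gel_io import GelMatrix, ModelConstants

__all__ = ["LrtResult", "fit_univariate", "lrt_classify", "lrt_table"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_TINY = 1e-300

# box constraints: |kappa|, |tau| <= 10 avoids the flat likelihood ridge
# where expression probabilities saturate indistinguishably close to 0/1
_KT_MAX = 10.0
_LOG_SIGMA_LO, _LOG_SIGMA_HI = math.log(1e-3), math.log(1e2)


@dataclass(frozen=True)
class LrtResult:
    spot_id: str
    loglik_full: float
    loglik_null: float
    statistic: float
    p_value: float
    significant: bool
    never_expressed: bool = False
    estimates: dict | None = None


class _SpotStats:
    """Sufficient statistics of one spot row, split by group."""

    def __init__(self, values, missing, is_case):
        self.groups = []
        for sel in (~is_case, is_case):
            v = np.asarray(values, dtype=float)[sel]
            m = np.asarray(missing, dtype=bool)[sel]
            obs = v[~m]
            self.groups.append((float(obs.sum()), float((obs**2).sum()), obs.size, int(m.sum())))
        self.n_obs_total = self.groups[0][2] + self.groups[1][2]


def _group_loglik(stats_g, mu, rho, sigma, d, nu):
    from .model import truncnorm_mass

    sv, sv2, n_obs, n_miss = stats_g
    total = 0.0
    if n_obs:
        lam = truncnorm_mass(mu, sigma, d, nu)
        quad = -0.5 * (sv2 - 2.0 * mu * sv + mu * mu * n_obs) / (sigma * sigma)
        total += quad + n_obs * (math.log(max(rho, _TINY)) - math.log(sigma) - _LOG_SQRT_2PI - math.log(lam))
    if n_miss:
        phi_d = ndtr((d - mu) / sigma)
        total += n_miss * math.log(max((1.0 - rho) + rho * phi_d, _TINY))
    return total


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def _make_objective(ss: _SpotStats, constants: ModelConstants, null: bool):
    d, nu = constants.d, constants.nu

    def neg_loglik(x):
        if null:
            mu, kappa, log_sigma = x
            delta = tau = 0.0
        else:
            mu, delta, kappa, tau, log_sigma = x
        if abs(kappa) > _KT_MAX or abs(tau) > _KT_MAX:
            return 1e12
        if not _LOG_SIGMA_LO <= log_sigma <= _LOG_SIGMA_HI:
            return 1e12
        sigma = math.exp(log_sigma)
        p0 = _expit(kappa)
        p1 = _expit(kappa + tau)
        ll = _group_loglik(ss.groups[0], mu, p0, sigma, d, nu)
        ll += _group_loglik(ss.groups[1], mu + delta, p1, sigma, d, nu)
        return -ll

    return neg_loglik


def _moment_start(ss: _SpotStats, null: bool):
    parts = []
    for sv, sv2, n_obs, n_miss in ss.groups:
        mean = sv / n_obs if n_obs else -5.0
        n = n_obs + n_miss
        frac = min(max(n_obs / n, 1.0 / (n + 1)), n / (n + 1))
        parts.append((mean, math.log(frac / (1.0 - frac))))
    mu0 = parts[0][0]
    delta0 = parts[1][0] - parts[0][0]
    kappa0 = max(min(parts[0][1], 2.94), -2.94)
    tau0 = max(min(parts[1][1] - parts[0][1], 5.0), -5.0)
    # pooled within-group spread
    var = 0.0
    n_tot = 0
    for (sv, sv2, n_obs, _), (mean, _k) in zip(ss.groups, parts):
        if n_obs:
            var += sv2 - 2 * mean * sv + mean * mean * n_obs
            n_tot += n_obs
    sigma0 = math.sqrt(var / n_tot) if n_tot > 1 and var > 0 else 0.7
    log_sigma0 = max(min(math.log(sigma0), _LOG_SIGMA_HI), _LOG_SIGMA_LO)
    if null:
        return np.array([mu0, kappa0, log_sigma0])
    return np.array([mu0, delta0, kappa0, tau0, log_sigma0])


def fit_univariate(
    values_row: np.ndarray,
    missing_row: np.ndarray,
    is_case: np.ndarray,
    constants: ModelConstants,
    null: bool,
    n_starts: int = 6,
    seed: int = 0,
) -> tuple[dict, float]:
    """Maximise one spot's censored-mixture likelihood.

    Multi-start local optimisation (moment-based start plus jittered
    restarts).  The full model is (mu, delta, kappa, tau, sigma); the null
    model pins delta = tau = 0.  A spot with no observed value in either
    group sits on the ML boundary p -> 0 with log likelihood 0 and is
    returned as "never expressed".
    """
    ss = _SpotStats(values_row, missing_row, is_case)
    if ss.n_obs_total == 0:
        est = {"mu": math.nan, "delta": 0.0, "kappa": -math.inf, "tau": 0.0, "sigma": math.nan,
               "never_expressed": True}
        return est, 0.0

    obj = _make_objective(ss, constants, null)
    x0 = _moment_start(ss, null)
    rng = np.random.default_rng(seed)
    jitter = np.array([1.0, 1.0, 0.5]) if null else np.array([1.0, 1.0, 1.0, 1.0, 0.5])
    best_x, best_f = None, math.inf
    for k in range(max(1, n_starts)):
        start = x0 if k == 0 else x0 + rng.normal(scale=jitter)
        res = optimize.minimize(obj, start, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if null:
        mu, kappa, log_sigma = best_x
        delta = tau = 0.0
    else:
        mu, delta, kappa, tau, log_sigma = best_x
    est = {"mu": float(mu), "delta": float(delta), "kappa": float(kappa), "tau": float(tau),
           "sigma": float(math.exp(log_sigma)), "never_expressed": False}
    return est, -best_f


def lrt_classify(
    gm: GelMatrix,
    alpha: float = 0.05,
    constants: ModelConstants | None = None,
    n_starts: int = 6,
    seed: int = 0,
) -> list[LrtResult]:
    """Per-spot likelihood ratio test of delta = tau = 0 against chi2(2)."""
    constants = constants or gm.constants
    is_case = gm.is_case
    out = []
    for i, sid in enumerate(gm.spot_ids):
        row, miss = gm.values[i], gm.missing_mask[i]
        est_f, ll_full = fit_univariate(row, miss, is_case, constants, null=False,
                                        n_starts=n_starts, seed=seed + i)
        if est_f["never_expressed"]:
            out.append(LrtResult(sid, 0.0, 0.0, 0.0, 1.0, False, never_expressed=True,
                                 estimates=est_f))
            continue
        est_0, ll_null = fit_univariate(row, miss, is_case, constants, null=True,
                                        n_starts=n_starts, seed=seed + i)
        stat = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(stats.chi2.sf(stat, df=2))
        out.append(LrtResult(sid, ll_full, ll_null, stat, p, p < alpha, estimates=est_f))
    return out


def lrt_table(results: list[LrtResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": [r.spot_id for r in results],
            "loglik_full": [r.loglik_full for r in results],
            "loglik_null": [r.loglik_null for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "never_expressed": [r.never_expressed for r in results],
        }
    )
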