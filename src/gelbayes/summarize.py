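"""Posterior summaries: HPD intervals, ESS, and DE classification.

A spot is called differentially expressed (DE) when the 95% highest
posterior density (HPD) interval of its intensity difference ``delta_s``
and/or its expression-propensity difference ``tau_s`` excludes zero — three
scenarios: intensity only, probability of expression only, or both.
Direction (up/down) is read off the sign of the ``delta_s`` HPD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import GLOBAL_PARAM_NAMES, ChainTrace

__all__ = [
    "SpotClassification",
    "hpd_interval",
    "ess",
    "classify_spots",
    "classification_table",
    "summarize_globals",
    "prior_posterior_densities",
    "count_classifications",
]


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Contiguous highest-posterior-density interval.

    Among all windows of ``ceil(mass * n)`` consecutive order statistics the
    shortest is returned; ties break to the lowest lower bound.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 samples for an HPD interval, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    w = int(math.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return float(x[i]), float(x[i + w - 1])


def ess(samples: np.ndarray) -> float:
    """Effective sample size by initial-positive-sequence truncation.

    ``n / (1 + 2 sum_k rho_k)`` with empirical autocorrelations summed until
    the first non-positive estimate; capped at ``n``.  A constant series has
    no autocorrelation information and returns ``n`` (flag separately).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples for an ESS estimate, got {n}")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0.0:
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        s += rho[k]
    return float(min(n, n / (1.0 + 2.0 * s)))


@dataclass(frozen=True)
class SpotClassification:
    """Per-spot DE call from the delta_s and tau_s marginal posteriors."""

    spot_id: str
    delta_mean: float
    delta_hpd: tuple[float, float]
    tau_mean: float
    tau_hpd: tuple[float, float]
    de_intensity: bool
    de_probability: bool
    direction: str  # "up" | "down" | "none"

    @property
    def de(self) -> bool:
        return self.de_intensity or self.de_probability


def classify_spots(trace: ChainTrace, mass: float = 0.95) -> list[SpotClassification]:
    """Three-scenario DE classification from the retained trace."""
    deltas = trace.local_columns("delta")
    taus = trace.local_columns("tau")
    out = []
    for j, sid in enumerate(trace.spot_ids):
        d_lo, d_hi = hpd_interval(deltas[:, j], mass)
        t_lo, t_hi = hpd_interval(taus[:, j], mass)
        de_int = d_lo > 0.0 or d_hi < 0.0
        de_prob = t_lo > 0.0 or t_hi < 0.0
        direction = "up" if d_lo > 0.0 else ("down" if d_hi < 0.0 else "none")
        out.append(
            SpotClassification(
                spot_id=sid,
                delta_mean=float(deltas[:, j].mean()),
                delta_hpd=(d_lo, d_hi),
                tau_mean=float(taus[:, j].mean()),
                tau_hpd=(t_lo, t_hi),
                de_intensity=de_int,
                de_probability=de_prob,
                direction=direction,
            )
        )
    return out


def classification_table(classes: list[SpotClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": [c.spot_id for c in classes],
            "delta_mean": [c.delta_mean for c in classes],
            "delta_hpd_lo": [c.delta_hpd[0] for c in classes],
            "delta_hpd_hi": [c.delta_hpd[1] for c in classes],
            "tau_mean": [c.tau_mean for c in classes],
            "tau_hpd_lo": [c.tau_hpd[0] for c in classes],
            "tau_hpd_hi": [c.tau_hpd[1] for c in classes],
            "de_intensity": [c.de_intensity for c in classes],
            "de_probability": [c.de_probability for c in classes],
            "de": [c.de for c in classes],
            "direction": [c.direction for c in classes],
        }
    )


def count_classifications(
    classes: list[SpotClassification],
    other_de_ids: set[str] | None = None,
) -> dict[str, int]:
    """Marginal DE counts, with an optional Venn-style overlap breakdown
    against a second method's DE spot set (e.g. the LRT baseline)."""
    de_ids = {c.spot_id for c in classes if c.de}
    counts = {
        "total": len(classes),
        "de": len(de_ids),
        "de_intensity": sum(c.de_intensity for c in classes),
        "de_probability": sum(c.de_probability for c in classes),
        "de_both": sum(c.de_intensity and c.de_probability for c in classes),
        "up": sum(c.direction == "up" for c in classes),
        "down": sum(c.direction == "down" for c in classes),
    }
    if other_de_ids is not None:
        other = set(other_de_ids)
        counts["other_de"] = len(other)
        counts["overlap"] = len(de_ids & other)
        counts["only_this"] = len(de_ids - other)
        counts["only_other"] = len(other - de_ids)
    return counts


# ---------------------------------------------------------------------------
# global-parameter summaries
# ---------------------------------------------------------------------------

def summarize_globals(trace: ChainTrace, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, HPD and ESS for the nine global parameters."""
    rows = []
    for name in GLOBAL_PARAM_NAMES:
        x = trace.column(name)
        lo, hi = hpd_interval(x, mass)
        constant = bool(np.all(x == x[0]))
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
                "ess": ess(x),
                "constant_chain": constant,
            }
        )
    return pd.DataFrame(rows)


def _prior_pdf(name: str, grid: np.ndarray) -> np.ndarray:
    """Prior density on the reported (natural) scale of each global parameter.

    Standard deviations carry inverse-gamma priors on their variances; the
    reported-scale density includes the |d sigma^2 / d sigma| = 2 sigma
    Jacobian.
    """
    if name == "mu_g":
        return stats.norm.pdf(grid, -3.0, 5.0)
    if name in ("mu_kappa", "mu_tau"):
        return stats.norm.pdf(grid, 0.0, 3.0)
    if name == "psi":
        return stats.uniform.pdf(grid, 0.001, 2.0 - 0.001)
    if name == "lambda_delta":
        return stats.expon.pdf(grid)
    if name == "phi_delta":
        return stats.beta.pdf(grid, 2.0, 2.0)
    if name in ("sigma_g", "sigma_kappa", "sigma_tau"):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = stats.invgamma.pdf(grid**2, 0.001, scale=0.001) * 2.0 * grid
        return np.where(grid > 0, out, 0.0)
    raise KeyError(name)


def prior_posterior_densities(
    trace: ChainTrace,
    parameters: list[str] | None = None,
    n_grid: int = 200,
) -> pd.DataFrame:
    """Plot-ready table of prior and kernel-density posterior curves.

    One block of ``n_grid`` rows per parameter with columns
    (parameter, value, prior_density, posterior_density).
    """
    parameters = parameters or list(GLOBAL_PARAM_NAMES)
    frames = []
    for name in parameters:
        x = trace.column(name)
        lo, hi = float(x.min()), float(x.max())
        pad = 0.25 * (hi - lo) if hi > lo else max(0.5, abs(lo) * 0.1)
        grid = np.linspace(lo - pad, hi + pad, n_grid)
        if np.std(x) > 0:
            post = stats.gaussian_kde(x)(grid)
        else:
            post = np.where(np.isclose(grid, lo), 1.0, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "value": grid,
                    "prior_density": _prior_pdf(name, grid),
                    "posterior_density": post,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def minimum_ess(trace: ChainTrace) -> float:
    """Smallest ESS across global parameters and the log posterior."""
    names = list(GLOBAL_PARAM_NAMES) + ["log_posterior"]
    return min(ess(trace.column(n)) for n in names)
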