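"""Adaptive block-updating Metropolis-Hastings sampler for the gel model.

The sampler walks over all local parameters (mu_s, delta_s, kappa_s, tau_s
per spot) and the nine global parameters, with three mixing aids:

* **Proposal tuning** — every proposal scale is rescaled once per tuning
  interval during burn-in by the quantile ratio
  ``sd_new = sd_cur * ndtri(rho_opt / 2) / ndtri(rho_cur / 2)``, driving the
  block's acceptance rate towards 0.44 (single-parameter blocks) or 0.234
  (multi-parameter blocks), with the current rate averaged over a longer
  window.  Adaptation is frozen after burn-in so the post-burn-in chain is a
  fixed-kernel sampler.
* **Block updating** — related parameters are proposed together under one
  accept/reject decision: (mu_g', sigma_g2'), (lambda_delta, phi_delta),
  (mu_kappa', sigma_kappa2'), (mu_tau', sigma_tau2') and each expansion
  multiplier on the global layer; (mu_s, delta_s) and (kappa_s, tau_s) per
  spot on the local layer — eight global blocks in all when expansion is on.
* **Parameter expansion** — each (mean, variance) pair is stored as primed
  parameters times a redundant multiplier alpha, e.g. ``mu_g = alpha_mu *
  mu_g'`` and ``sigma_g^2 = alpha_mu^2 * sigma_g2'``.  The alphas carry
  Uniform(0.01, 10) priors; priors on the natural-scale parameters are
  unchanged, so the natural-scale posterior is exactly preserved while
  mixing near zero variance improves.

Proposals follow the parameter supports: truncated normals for scales,
variances and the expansion multipliers (with the exact truncation-mass
Hastings correction), a logit-scale normal for the up-regulated proportion
phi_delta (with its Jacobian correction), and plain normals elsewhere.

Because spots are conditionally independent given the globals, the per-spot
local blocks are updated in one sweep per iteration with a shared proposal
scale per block kind; the per-iteration cost is O(S) via per-spot
sufficient statistics.  The iteration loop itself is compiled
(:mod:`gelbayes._kernel`); this module owns initialisation, the adaptive
tuning schedule, and the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, gammaln, ndtr, ndtri

from . import _kernel
from .gel_io import GelMatrix, ModelConstants
from .model import LOG_FLOOR, GlobalParams, LocalParams, expression_prob

__all__ = [
    "ChainConfig",
    "ChainTrace",
    "run_chain",
    "write_trace",
    "read_trace",
    "adapt_sd",
    "mh_accept",
    "truncnorm_propose",
    "logit_normal_propose",
    "sample_scalar_target",
    "default_init",
    "GLOBAL_PARAM_NAMES",
    "ALPHA_NAMES",
    "BLOCK_NAMES",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_TINY = 1e-300
_MASS_EPS = 1e-14
_SQRT1_2 = math.sqrt(0.5)

GLOBAL_PARAM_NAMES = (
    "mu_g",
    "sigma_g",
    "psi",
    "lambda_delta",
    "phi_delta",
    "mu_kappa",
    "sigma_kappa",
    "mu_tau",
    "sigma_tau",
)
ALPHA_NAMES = ("alpha_mu", "alpha_kappa", "alpha_tau")

#: update-block order; indices match the kernel's proposal-sd / counter slots
BLOCK_NAMES = (
    "mu_sigma_g",
    "alpha_mu",
    "lambda_phi",
    "psi",
    "mu_sigma_kappa",
    "alpha_kappa",
    "mu_sigma_tau",
    "alpha_tau",
    "local_mu_delta",
    "local_kappa_tau",
)

#: single-parameter blocks target acceptance 0.44, multi-parameter 0.234
SINGLE_BLOCKS = {"alpha_mu", "psi", "alpha_kappa", "alpha_tau"}


# ---------------------------------------------------------------------------
# proposal kernels and MH primitives (reference API; the compiled kernel
# mirrors these exactly)
# ---------------------------------------------------------------------------

def adapt_sd(sd_cur: float, rho_cur: float, rho_opt: float) -> float:
    """Rescale a proposal sd by the standard-normal quantile ratio.

    Acceptance above target grows the step, below target shrinks it.
    """
    if not (0.0 < rho_cur < 1.0 and 0.0 < rho_opt < 1.0):
        raise ValueError("acceptance ratios must lie strictly in (0, 1)")
    return float(sd_cur * ndtri(rho_opt / 2.0) / ndtri(rho_cur / 2.0))


def mh_accept(log_post_current: float, log_post_candidate: float, log_hastings: float, rng) -> bool:
    """One Metropolis-Hastings decision; draws exactly one uniform."""
    u = rng.uniform()
    if log_post_candidate <= LOG_FLOOR or not math.isfinite(log_post_candidate):
        return False
    log_alpha = (log_post_candidate - log_post_current) + log_hastings
    return math.log(u) < log_alpha


def _phi_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x * _SQRT1_2)


def truncnorm_propose(rng, current: float, sd: float, lower: float = -math.inf, upper: float = math.inf):
    """Draw from a normal centred at ``current`` truncated to [lower, upper].

    Returns ``(candidate, log_correction)`` where the correction is the log
    Hastings ratio contribution ``log q(cur | cand) - log q(cand | cur)``;
    the normal kernels cancel, leaving the ratio of truncation masses.
    """
    a = _phi_cdf((lower - current) / sd) if math.isfinite(lower) else 0.0
    b = _phi_cdf((upper - current) / sd) if math.isfinite(upper) else 1.0
    mass_cur = b - a
    if mass_cur < _MASS_EPS:
        return current, 0.0  # degenerate window: stay put
    u = rng.uniform()
    cand = current + sd * float(ndtri(a + u * mass_cur))
    cand = min(max(cand, lower), upper)
    a2 = _phi_cdf((lower - cand) / sd) if math.isfinite(lower) else 0.0
    b2 = _phi_cdf((upper - cand) / sd) if math.isfinite(upper) else 1.0
    mass_cand = max(b2 - a2, _MASS_EPS)
    return cand, math.log(mass_cur) - math.log(mass_cand)


def logit_normal_propose(rng, current: float, sd: float):
    """Random-walk proposal on the logit scale for a (0, 1) parameter.

    Returns ``(candidate, log_correction)``; the correction is the Jacobian
    ratio ``log[cand (1 - cand)] - log[cur (1 - cur)]``.
    """
    logit = math.log(current / (1.0 - current))
    cand = float(expit(logit + sd * rng.standard_normal()))
    cand = min(max(cand, 1e-12), 1.0 - 1e-12)
    corr = math.log(cand * (1.0 - cand)) - math.log(current * (1.0 - current))
    return cand, corr


# ---------------------------------------------------------------------------
# tuning bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _BlockTuner:
    sd: float
    target: float
    # (accepts, attempts) per completed tuning interval
    chunks: list = field(default_factory=list)
    acc: int = 0
    att: int = 0

    def record(self, accepts: int, attempts: int) -> None:
        self.acc += accepts
        self.att += attempts

    def update(self, n_keep: int, sd_min: float = 1e-8, sd_max: float = 1e8) -> None:
        self.chunks.append((self.acc, self.att))
        self.acc = 0
        self.att = 0
        recent = self.chunks[-n_keep:]
        attempts = sum(c[1] for c in recent)
        if attempts == 0:
            return
        accepts = sum(c[0] for c in recent)
        lo = 1.0 / attempts
        rho_cur = min(max(accepts / attempts, lo), 1.0 - lo)
        self.sd = min(max(adapt_sd(self.sd, rho_cur, self.target), sd_min), sd_max)


# ---------------------------------------------------------------------------
# chain configuration and trace container
# ---------------------------------------------------------------------------

@dataclass
class ChainConfig:
    """Sampler settings.

    ``burnin_frac`` of the iterations is discarded and is also the window in
    which proposal scales adapt.  ``thin`` records every thin-th state.
    """

    iterations: int
    thin: int = 100
    burnin_frac: float = 0.1
    seed: int = 0
    expansion: bool = True
    tune: bool = True
    target_accept_single: float = 0.44
    target_accept_multi: float = 0.234
    tune_interval: int = 500
    tune_window: int = 3000
    init_proposal_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.iterations < self.thin:
            raise ValueError("iterations must be >= thin")
        if not 0.0 <= self.burnin_frac < 1.0:
            raise ValueError("burnin_frac must lie in [0, 1)")


@dataclass
class ChainTrace:
    """Thinned chain states on the natural scale.

    ``states``/``values`` hold every recorded state including burn-in;
    :attr:`data` exposes the retained (post-burn-in) block that all
    summaries consume.
    """

    param_names: list[str]
    states: np.ndarray
    values: np.ndarray
    spot_ids: list[str]
    iterations: int
    thin: int
    burnin_frac: float
    seed: int
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    final_proposal_sd: dict[str, float] = field(default_factory=dict)

    @property
    def n_burn_rows(self) -> int:
        burn_until = self.burnin_frac * self.iterations
        return int(np.sum(self.states <= burn_until))

    @property
    def data(self) -> np.ndarray:
        """Retained post-burn-in rows."""
        return self.values[self.n_burn_rows:]

    @property
    def n_retained(self) -> int:
        return self.values.shape[0] - self.n_burn_rows

    def column(self, name: str, retained: bool = True) -> np.ndarray:
        j = self.param_names.index(name)
        return (self.data if retained else self.values)[:, j]

    def local_columns(self, kind: str, retained: bool = True) -> np.ndarray:
        """(rows, S) matrix for one local parameter kind: mu/delta/kappa/tau."""
        cols = [self.param_names.index(f"{kind}.{sid}") for sid in self.spot_ids]
        return (self.data if retained else self.values)[:, cols]

    def to_dataframe(self, retained: bool = True):
        import pandas as pd

        rows = self.n_burn_rows if retained else 0
        return pd.DataFrame(
            self.values[rows:], columns=self.param_names, index=self.states[rows:]
        ).rename_axis("state")


def write_trace(trace: ChainTrace, path: str | Path) -> None:
    """Write a Tracer-compatible tab-delimited trace log."""
    if trace.values.shape[0] == 0:
        raise ValueError("empty trace")
    with open(path, "w") as fh:
        fh.write("# gelbayes MCMC trace\n")
        fh.write(f"# iterations={trace.iterations} thin={trace.thin} "
                 f"burnin_frac={trace.burnin_frac} seed={trace.seed}\n")
        fh.write(f"# spot_ids={','.join(trace.spot_ids)}\n")
        fh.write("state\t" + "\t".join(trace.param_names) + "\n")
        for state, row in zip(trace.states, trace.values):
            fh.write(str(int(state)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_trace(path: str | Path) -> ChainTrace:
    """Read a trace log written by :func:`write_trace`."""
    meta: dict[str, float] = {}
    spot_ids: list[str] = []
    header: list[str] = []
    states = []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("spot_ids="):
                    spot_ids = body[len("spot_ids="):].split(",")
                else:
                    for token in body.split():
                        if "=" in token:
                            k, v = token.split("=", 1)
                            meta[k] = float(v)
                continue
            if not header:
                header = line.split("\t")[1:]
                continue
            parts = line.split("\t")
            states.append(int(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    return ChainTrace(
        param_names=header,
        states=np.asarray(states),
        values=np.asarray(rows),
        spot_ids=spot_ids,
        iterations=int(meta.get("iterations", states[-1] if states else 0)),
        thin=int(meta.get("thin", 1)),
        burnin_frac=float(meta.get("burnin_frac", 0.0)),
        seed=int(meta.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# per-spot sufficient statistics and scalar prior (shared with the kernel)
# ---------------------------------------------------------------------------

class _GroupStats:
    """Per-spot sufficient statistics for one group's gels.

    The censored-mixture likelihood depends on the data only through, per
    spot: the sum and sum of squares of observed intensities and the counts
    of observed and missing cells.
    """

    def __init__(self, values: np.ndarray, missing: np.ndarray):
        obs = ~missing
        v = np.where(obs, np.nan_to_num(values), 0.0)
        self.sv = v.sum(axis=1)
        self.sv2 = (v * v).sum(axis=1)
        self.n_obs = obs.sum(axis=1).astype(float)
        self.n_miss = missing.sum(axis=1).astype(float)

    def geometry(self, mu_x: np.ndarray, sigma: float, d: float, nu: float):
        """Parts depending on (mu_x, sigma) only: quad term, Phi_d, log lambda."""
        from .model import truncnorm_mass

        inv2 = 1.0 / (sigma * sigma)
        quad = -0.5 * inv2 * (self.sv2 - 2.0 * mu_x * self.sv + mu_x * mu_x * self.n_obs)
        phi_d = ndtr((d - mu_x) / sigma)
        loglam = np.log(truncnorm_mass(mu_x, sigma, d, nu))
        return quad, phi_d, loglam

    def assemble(self, geom, rho: np.ndarray, sigma: float) -> np.ndarray:
        quad, phi_d, loglam = geom
        log_rho = np.log(np.maximum(rho, _TINY))
        miss_mass = np.log(np.maximum((1.0 - rho) + rho * phi_d, _TINY))
        return (
            quad
            + self.n_obs * (log_rho - math.log(sigma) - _LOG_SQRT_2PI - loglam)
            + self.n_miss * miss_mass
        )


_IG_SHAPE = 0.001
_IG_RATE = 0.001
_IG_CONST = _IG_SHAPE * math.log(_IG_RATE) - float(gammaln(_IG_SHAPE))
_PSI_LOGWIDTH = math.log(2.0 - 0.001)


def _ig_logpdf(v: float) -> float:
    return _IG_CONST - (_IG_SHAPE + 1.0) * math.log(v) - _IG_RATE / v


def _fast_prior(mu_g, var_g, psi, lam, phi, mu_k, var_k, mu_t, var_t) -> float:
    """Scalar-math global log prior on (mean, variance) coordinates.

    Agrees exactly with :func:`gelbayes.model.global_log_prior`; the
    expansion multipliers' Uniform(0.01, 10) priors are flat and enter only
    through their support bounds, enforced at proposal time.
    """
    if not (var_g > 0 and var_k > 0 and var_t > 0 and lam > 0
            and 0.0 < phi < 1.0 and 0.001 <= psi <= 2.0):
        return -math.inf
    z = (mu_g + 3.0) / 5.0
    lp = -0.5 * z * z - math.log(5.0) - _LOG_SQRT_2PI
    lp += _ig_logpdf(var_g)
    lp += -_PSI_LOGWIDTH
    lp += -lam
    lp += math.log(6.0) + math.log(phi) + math.log(1.0 - phi)
    z = mu_k / 3.0
    lp += -0.5 * z * z - math.log(3.0) - _LOG_SQRT_2PI
    lp += _ig_logpdf(var_k)
    z = mu_t / 3.0
    lp += -0.5 * z * z - math.log(3.0) - _LOG_SQRT_2PI
    lp += _ig_logpdf(var_t)
    return lp


def _normal_logpdf_vec(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI


def _mod_laplace_vec(delta: np.ndarray, lam: float, phi: float) -> np.ndarray:
    log_lam = math.log(lam)
    return np.where(
        delta < 0,
        math.log(1.0 - phi) + log_lam + lam * delta,
        math.log(phi) + log_lam - lam * delta,
    )


def default_init(gm: GelMatrix) -> tuple[LocalParams, GlobalParams]:
    """Moment-based starting state.

    Spot means from observed averages (fallback -3), kappa from the logit of
    the observed expression fraction clamped to +/-2.94, delta = tau = 0;
    globals by method of moments over the locals with prior-centre fallbacks
    for quantities the degenerate start leaves undefined.
    """
    obs = ~gm.missing_mask
    n_obs = obs.sum(axis=1)
    mu = np.where(
        n_obs > 0,
        np.where(obs, np.nan_to_num(gm.values), 0.0).sum(axis=1) / np.maximum(n_obs, 1),
        -3.0,
    )
    frac = np.clip(n_obs / gm.n_gels, 1e-3, 1.0 - 1e-3)
    kappa = np.clip(np.log(frac / (1.0 - frac)), -2.94, 2.94)
    local = LocalParams(mu=mu, delta=np.zeros_like(mu), kappa=kappa, tau=np.zeros_like(mu))

    sigma_g = float(max(np.std(mu), 0.1))
    resid = np.where(obs, gm.values - mu[:, None], np.nan)
    pooled = float(np.nanstd(resid)) if np.any(obs) else 0.5
    psi = float(min(max(pooled / sigma_g if pooled > 0 else 0.5, 0.01), 2.0))
    const = gm.constants
    g = GlobalParams(
        mu_g=float(min(max(np.mean(mu), const.d), const.nu)),
        sigma_g=sigma_g,
        psi=psi,
        lambda_delta=1.0,
        phi_delta=0.5,
        mu_kappa=float(np.mean(kappa)),
        sigma_kappa=float(max(np.std(kappa), 0.1)),
        mu_tau=0.0,
        sigma_tau=1.0,
    )
    return local, g


# ---------------------------------------------------------------------------
# the sampler driver
# ---------------------------------------------------------------------------

class _Sampler:
    def __init__(
        self,
        gm: GelMatrix,
        config: ChainConfig,
        constants: ModelConstants | None = None,
        init: tuple[LocalParams, GlobalParams] | None = None,
    ):
        self.gm = gm
        self.cfg = config
        self.const = constants or gm.constants
        self.rng = np.random.default_rng(config.seed)
        is_case = gm.is_case
        self.g0 = _GroupStats(gm.values[:, ~is_case], gm.missing_mask[:, ~is_case])
        self.g1 = _GroupStats(gm.values[:, is_case], gm.missing_mask[:, is_case])
        self.S = gm.n_spots

        if init is None:
            init = default_init(gm)
        self._set_state(*init)
        if not math.isfinite(self.log_posterior()):
            # fall back to a generic in-support start
            local = LocalParams(
                mu=np.full(self.S, -3.0),
                delta=np.zeros(self.S),
                kappa=np.zeros(self.S),
                tau=np.zeros(self.S),
            )
            g = GlobalParams(-3.0, 1.0, 0.7, 1.0, 0.5, 0.0, 1.0, 0.0, 1.0)
            self._set_state(local, g)
            if not math.isfinite(self.log_posterior()):
                raise RuntimeError("could not find a finite-posterior initial state")

        names = [
            b for b in BLOCK_NAMES
            if config.expansion or not b.startswith("alpha")
        ]
        self.tuners = {
            name: _BlockTuner(
                sd=config.init_proposal_sd,
                target=(config.target_accept_single if name in SINGLE_BLOCKS
                        else config.target_accept_multi),
            )
            for name in names
        }
        self.post_acc = {name: [0, 0] for name in names}

    def _set_state(self, local: LocalParams, g: GlobalParams) -> None:
        if not g.in_support():
            raise ValueError("initial global parameters out of support")
        # sampler support constraints (enforced on the natural scale)
        if not self.const.d <= g.mu_g <= self.const.nu:
            raise ValueError(f"initial mu_g must lie in [{self.const.d}, {self.const.nu}]")
        if min(g.sigma_g, g.sigma_kappa, g.sigma_tau) < 0.01 or g.lambda_delta < 0.01:
            raise ValueError("initial scale parameters must be >= 0.01")
        self.local = local.copy()
        # flat expansion-scale state vector (alphas start at 1, primed = natural)
        self.gvec = np.array([
            g.mu_g, g.sigma_g**2, 1.0, g.psi, g.lambda_delta, g.phi_delta,
            g.mu_kappa, g.sigma_kappa**2, 1.0, g.mu_tau, g.sigma_tau**2, 1.0,
        ])
        self._refresh_caches()

    def natural(self) -> GlobalParams:
        g = self.gvec
        return GlobalParams(
            mu_g=g[2] * g[0],
            sigma_g=math.sqrt(g[2] * g[2] * g[1]),
            psi=g[3],
            lambda_delta=g[4],
            phi_delta=g[5],
            mu_kappa=g[8] * g[6],
            sigma_kappa=math.sqrt(g[8] * g[8] * g[7]),
            mu_tau=g[11] * g[9],
            sigma_tau=math.sqrt(g[11] * g[11] * g[10]),
        )

    def _refresh_caches(self) -> None:
        nat = self.natural()
        d, nu = self.const.d, self.const.nu
        sig = nat.sigma_s
        self.geom0 = [np.ascontiguousarray(a) for a in
                      self.g0.geometry(self.local.mu, sig, d, nu)]
        self.geom1 = [np.ascontiguousarray(a) for a in
                      self.g1.geometry(self.local.mu + self.local.delta, sig, d, nu)]
        self.rho0 = expression_prob(self.local.kappa)
        self.rho1 = expression_prob(self.local.kappa, self.local.tau)
        self.ll = self.g0.assemble(self.geom0, self.rho0, sig) + self.g1.assemble(self.geom1, self.rho1, sig)
        self.gl_mu = _normal_logpdf_vec(self.local.mu, nat.mu_g, nat.sigma_g)
        self.gl_delta = _mod_laplace_vec(self.local.delta, nat.lambda_delta, nat.phi_delta)
        self.gl_kappa = _normal_logpdf_vec(self.local.kappa, nat.mu_kappa, nat.sigma_kappa)
        self.gl_tau = _normal_logpdf_vec(self.local.tau, nat.mu_tau, nat.sigma_tau)
        self.sums = np.array([
            self.ll.sum(), self.gl_mu.sum(), self.gl_delta.sum(),
            self.gl_kappa.sum(), self.gl_tau.sum(),
            _fast_prior(nat.mu_g, nat.sigma_g**2, nat.psi, nat.lambda_delta,
                        nat.phi_delta, nat.mu_kappa, nat.sigma_kappa**2,
                        nat.mu_tau, nat.sigma_tau**2),
        ])

    def _refresh_sums(self) -> None:
        # re-anchor the incrementally updated totals (bounds float drift)
        nat = self.natural()
        self.sums[0] = self.ll.sum()
        self.sums[1] = self.gl_mu.sum()
        self.sums[2] = self.gl_delta.sum()
        self.sums[3] = self.gl_kappa.sum()
        self.sums[4] = self.gl_tau.sum()
        self.sums[5] = _fast_prior(nat.mu_g, nat.sigma_g**2, nat.psi,
                                   nat.lambda_delta, nat.phi_delta,
                                   nat.mu_kappa, nat.sigma_kappa**2,
                                   nat.mu_tau, nat.sigma_tau**2)

    def log_posterior(self) -> float:
        return float(self.sums.sum())

    def run(self) -> ChainTrace:
        cfg = self.cfg
        burn_until = int(round(cfg.burnin_frac * cfg.iterations))
        n_keep = max(1, cfg.tune_window // cfg.tune_interval)
        param_names = (
            list(GLOBAL_PARAM_NAMES)
            + list(ALPHA_NAMES)
            + [f"{k}.{sid}" for sid in self.gm.spot_ids for k in ("mu", "delta", "kappa", "tau")]
            + ["log_posterior"]
        )
        n_rows = cfg.iterations // cfg.thin
        rec = np.empty((n_rows, len(param_names)))
        rec_states = np.empty(n_rows, dtype=np.int64)
        row_ptr = 0
        sds = np.zeros(len(BLOCK_NAMES))
        acc = np.zeros((len(BLOCK_NAMES), 2), dtype=np.int64)
        post_chunk = 200_000

        it = 0
        while it < cfg.iterations:
            if it < burn_until:
                chunk = min(cfg.tune_interval, burn_until - it)
            else:
                chunk = min(post_chunk, cfg.iterations - it)
            for i, name in enumerate(BLOCK_NAMES):
                sds[i] = self.tuners[name].sd if name in self.tuners else 0.0
            acc[:] = 0
            row_ptr = _kernel.run_iters(
                self.rng, it, chunk, cfg.expansion,
                self.g0.sv, self.g0.sv2, self.g0.n_obs, self.g0.n_miss,
                self.g1.sv, self.g1.sv2, self.g1.n_obs, self.g1.n_miss,
                self.local.mu, self.local.delta, self.local.kappa, self.local.tau,
                self.gvec,
                self.ll, self.gl_mu, self.gl_delta, self.gl_kappa, self.gl_tau,
                self.rho0, self.rho1,
                self.geom0[0], self.geom0[1], self.geom0[2],
                self.geom1[0], self.geom1[1], self.geom1[2],
                self.sums, sds, acc,
                self.const.d, self.const.nu,
                cfg.thin, rec, rec_states, row_ptr,
            )
            it += chunk
            in_burnin = it <= burn_until
            for i, name in enumerate(BLOCK_NAMES):
                if name not in self.tuners:
                    continue
                self.tuners[name].record(int(acc[i, 0]), int(acc[i, 1]))
                if not in_burnin:
                    pa = self.post_acc[name]
                    pa[0] += int(acc[i, 0])
                    pa[1] += int(acc[i, 1])
            if cfg.tune and in_burnin and it % cfg.tune_interval == 0:
                for tuner in self.tuners.values():
                    tuner.update(n_keep)
            self._refresh_sums()

        rates = {
            name: (pa[0] / pa[1] if pa[1] else math.nan)
            for name, pa in self.post_acc.items()
        }
        return ChainTrace(
            param_names=param_names,
            states=rec_states[:row_ptr],
            values=rec[:row_ptr],
            spot_ids=list(self.gm.spot_ids),
            iterations=cfg.iterations,
            thin=cfg.thin,
            burnin_frac=cfg.burnin_frac,
            seed=cfg.seed,
            acceptance_rates=rates,
            final_proposal_sd={k: t.sd for k, t in self.tuners.items()},
        )


def run_chain(
    gm: GelMatrix,
    config: ChainConfig,
    constants: ModelConstants | None = None,
    init: tuple[LocalParams, GlobalParams] | None = None,
) -> ChainTrace:
    """Run the adaptive block-updating MH sampler and return a thinned trace.

    Identical data + config (including seed) give bit-identical traces.
    """
    return _Sampler(gm, config, constants, init).run()


# ---------------------------------------------------------------------------
# generic scalar-target sampler (sampler-correctness hook)
# ---------------------------------------------------------------------------

def sample_scalar_target(
    log_pdf,
    iterations: int,
    seed: int,
    init: float = 0.0,
    init_sd: float = 0.5,
    burnin_frac: float = 0.1,
    tune: bool = True,
    target: float = 0.44,
    tune_interval: int = 500,
    tune_window: int = 3000,
    freeze_after_burnin: bool = True,
) -> np.ndarray:
    """Run the same adaptive random-walk MH machinery on a 1-D target.

    Used to validate the sampler core against targets with known moments
    (detailed-balance smoke test); returns the post-burn-in samples.
    """
    rng = np.random.default_rng(seed)
    tuner = _BlockTuner(sd=init_sd, target=target)
    n_keep = max(1, tune_window // tune_interval)
    burn_until = int(round(burnin_frac * iterations))
    x = init
    lp = log_pdf(x)
    out = np.empty(iterations - burn_until)
    for it in range(1, iterations + 1):
        cand = x + tuner.sd * rng.standard_normal()
        lp_cand = log_pdf(cand)
        acc = mh_accept(lp, lp_cand, 0.0, rng)
        if acc:
            x, lp = cand, lp_cand
        tuner.record(int(acc), 1)
        adapting = tune and (it <= burn_until or not freeze_after_burnin)
        if adapting and it % tune_interval == 0:
            tuner.update(n_keep)
        if it > burn_until:
            out[it - burn_until - 1] = x
    return out
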