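import math

import numpy as np
import pytest
from scipy import stats

from gelbayes import (
    ChainConfig,
    GlobalParams,
    LocalParams,
    joint_log_posterior,
    read_trace,
    run_chain,
    write_trace,
)
from gelbayes.mcmc import (
    GLOBAL_PARAM_NAMES,
    adapt_sd,
    logit_normal_propose,
    mh_accept,
    sample_scalar_target,
    truncnorm_propose,
)


class TestAdaptSd:
    def test_at_target_unchanged(self):
        assert np.isclose(adapt_sd(0.5, 0.234, 0.234), 0.5)

    def test_quantile_ratio_oracle(self):
        # rho_cur = 0.5, rho_opt = 0.234: factor Phi^-1(0.117)/Phi^-1(0.25)
        factor = stats.norm.ppf(0.117) / stats.norm.ppf(0.25)
        assert np.isclose(adapt_sd(1.0, 0.5, 0.234), factor)
        assert 1.7 < factor < 1.8

    def test_monotone_in_acceptance(self):
        lo = adapt_sd(1.0, 0.1, 0.234)
        hi = adapt_sd(1.0, 0.6, 0.234)
        assert lo < 1.0 < hi

    def test_rejects_degenerate_rates(self):
        with pytest.raises(ValueError):
            adapt_sd(1.0, 0.0, 0.234)


class TestMhAccept:
    def test_sure_accept_and_reject(self):
        rng = np.random.default_rng(0)
        assert mh_accept(-10.0, -10.0, 0.0, rng)  # alpha = 1
        assert not mh_accept(-10.0, -math.inf, 0.0, rng)

    def test_long_run_frequency(self):
        rng = np.random.default_rng(1)
        delta = -0.5
        n = 20000
        hits = sum(mh_accept(0.0, delta, 0.0, rng) for _ in range(n))
        expect = math.exp(delta)
        assert abs(hits / n - expect) < 4.0 * math.sqrt(expect * (1 - expect) / n)


class TestProposals:
    def test_symmetric_normal_case_no_correction(self):
        rng = np.random.default_rng(2)
        cand, corr = truncnorm_propose(rng, 0.3, 0.5)  # unbounded
        assert corr == 0.0

    def test_truncnorm_respects_bounds_and_correction(self):
        rng = np.random.default_rng(3)
        lo = 0.01
        for _ in range(200):
            cand, corr = truncnorm_propose(rng, 0.05, 0.5, lo, math.inf)
            assert cand >= lo
        # correction equals the log ratio of truncation masses
        cand, corr = truncnorm_propose(rng, 0.05, 0.5, lo, math.inf)
        z_cur = stats.norm.sf(lo, 0.05, 0.5)
        z_cand = stats.norm.sf(lo, cand, 0.5)
        assert np.isclose(corr, math.log(z_cur) - math.log(z_cand), atol=1e-9)

    def test_truncnorm_draws_match_distribution(self):
        rng = np.random.default_rng(4)
        draws = np.array([truncnorm_propose(rng, 0.2, 0.5, 0.0, 1.0)[0] for _ in range(4000)])
        a, b = (0.0 - 0.2) / 0.5, (1.0 - 0.2) / 0.5
        ks = stats.kstest(draws, stats.truncnorm(a, b, loc=0.2, scale=0.5).cdf)
        assert ks.pvalue > 0.001

    def test_logit_normal_stays_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for phi in (0.01, 0.5, 0.99):
            for _ in range(100):
                cand, corr = logit_normal_propose(rng, phi, 2.0)
                assert 0.0 < cand < 1.0
        cand, corr = logit_normal_propose(rng, 0.4, 1.0)
        assert np.isclose(
            corr, math.log(cand * (1 - cand)) - math.log(0.4 * 0.6), atol=1e-12
        )


class TestScalarTargetSampler:
    def test_standard_normal_moments(self):
        x = sample_scalar_target(lambda v: -0.5 * v * v, 60_000, seed=6)
        n_eff = len(x) / 10.0  # conservative autocorrelation discount
        assert abs(x.mean()) < 3.0 / math.sqrt(n_eff)
        assert abs(x.var() - 1.0) < 3.0 * math.sqrt(2.0 / n_eff)

    def test_freezing_tuning_preserves_target(self):
        frozen = sample_scalar_target(lambda v: -0.5 * v * v, 60_000, seed=7,
                                      freeze_after_burnin=True)
        tuned = sample_scalar_target(lambda v: -0.5 * v * v, 60_000, seed=8,
                                     freeze_after_burnin=False)
        for x in (frozen, tuned):
            n_eff = len(x) / 10.0
            assert abs(x.mean()) < 3.0 / math.sqrt(n_eff)
            assert abs(x.var() - 1.0) < 3.0 * math.sqrt(2.0 / n_eff)


class TestRunChain:
    def test_trace_shape_arithmetic(self, sim1_small):
        cfg = ChainConfig(iterations=10_000, thin=100, burnin_frac=0.1, seed=1)
        tr = run_chain(sim1_small.gel_matrix, cfg)
        assert tr.values.shape[0] == 100
        assert tr.n_retained == 90
        S = sim1_small.gel_matrix.n_spots
        assert len(tr.param_names) == 9 + 3 + 4 * S + 1

    def test_same_seed_bit_identical(self, sim1_small):
        cfg = ChainConfig(iterations=5_000, thin=100, seed=42)
        t1 = run_chain(sim1_small.gel_matrix, cfg)
        t2 = run_chain(sim1_small.gel_matrix, cfg)
        assert np.array_equal(t1.values, t2.values)
        t3 = run_chain(sim1_small.gel_matrix, ChainConfig(iterations=5_000, thin=100, seed=43))
        assert not np.array_equal(t1.values, t3.values)

    def test_natural_scale_invariants_hold_throughout(self, sim1_small_trace):
        tr = sim1_small_trace
        full = tr.values  # including burn-in rows
        names = tr.param_names
        assert np.all(full[:, names.index("sigma_g")] > 0)
        psi = full[:, names.index("psi")]
        assert np.all((psi >= 0.001) & (psi <= 2.0))
        assert np.all(full[:, names.index("lambda_delta")] > 0)
        phi = full[:, names.index("phi_delta")]
        assert np.all((phi > 0) & (phi < 1))
        assert np.all(full[:, names.index("sigma_kappa")] > 0)
        assert np.all(full[:, names.index("sigma_tau")] > 0)
        alphas = full[:, [names.index(a) for a in ("alpha_mu", "alpha_kappa", "alpha_tau")]]
        assert np.all((alphas >= 0.01) & (alphas <= 10.0))
        assert np.all(np.isfinite(full[:, -1]))

    def test_recorded_log_posterior_matches_reference(self, sim1_small, sim1_small_trace):
        """The kernel's cached log posterior equals an independent full
        recomputation from the recorded parameter state."""
        tr = sim1_small_trace
        gm = sim1_small.gel_matrix
        idx = [0, len(tr.states) // 2, len(tr.states) - 1]
        for i in idx:
            row = tr.values[i]
            g = GlobalParams(*[row[tr.param_names.index(n)] for n in GLOBAL_PARAM_NAMES])
            local = LocalParams(
                tr.local_columns("mu", retained=False)[i],
                tr.local_columns("delta", retained=False)[i],
                tr.local_columns("kappa", retained=False)[i],
                tr.local_columns("tau", retained=False)[i],
            )
            ref = joint_log_posterior(gm, local, g)
            assert abs(ref - row[-1]) < 1e-7

    def test_acceptance_rates_reasonable(self, sim1_small_trace):
        for name, rate in sim1_small_trace.acceptance_rates.items():
            assert 0.05 < rate < 0.8, f"block {name} acceptance {rate}"

    def test_alpha_fixed_without_expansion(self, sim1_small):
        cfg = ChainConfig(iterations=5_000, thin=100, seed=2, expansion=False)
        tr = run_chain(sim1_small.gel_matrix, cfg)
        for a in ("alpha_mu", "alpha_kappa", "alpha_tau"):
            assert np.all(tr.column(a, retained=False) == 1.0)

    def test_all_missing_spot_row_is_permitted(self):
        from gelbayes import GelMatrix

        values = np.array([[np.nan] * 6, [-5.0, -4.8, -5.2, -5.1, -4.9, -5.0]])
        gm = GelMatrix(
            values=values,
            missing_mask=np.isnan(values),
            spot_ids=["empty", "full"],
            gel_ids=[f"g{i}" for i in range(6)],
            groups=["control"] * 3 + ["case"] * 3,
        )
        tr = run_chain(gm, ChainConfig(iterations=2_000, thin=100, seed=0))
        assert np.all(np.isfinite(tr.values[:, -1]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=50, thin=100)
        with pytest.raises(ValueError):
            ChainConfig(iterations=1000, thin=10, burnin_frac=1.0)


class TestTraceIO:
    def test_round_trip(self, tmp_path, sim1_small_trace):
        p = tmp_path / "trace.log"
        write_trace(sim1_small_trace, p)
        tr2 = read_trace(p)
        assert tr2.param_names == sim1_small_trace.param_names
        assert np.array_equal(tr2.states, sim1_small_trace.states)
        assert np.array_equal(tr2.values, sim1_small_trace.values)
        assert tr2.thin == sim1_small_trace.thin
        assert tr2.n_burn_rows == sim1_small_trace.n_burn_rows
        assert tr2.spot_ids == sim1_small_trace.spot_ids

    def test_file_layout(self, tmp_path, sim1_small_trace):
        p = tmp_path / "trace.log"
        write_trace(sim1_small_trace, p)
        lines = p.read_text().splitlines()
        comments = [ln for ln in lines if ln.startswith("#")]
        data = [ln for ln in lines if not ln.startswith("#")]
        assert len(comments) >= 2
        assert data[0].startswith("state\t")
        assert len(data) - 1 == sim1_small_trace.values.shape[0]
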