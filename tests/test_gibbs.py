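"""Gibbs machinery: initialisation, conjugate updates, determinism, and the
serial/bulk-synchronous schedules."""

import math

import numpy as np
import pytest
from scipy import stats

from bayesw.core import EULER_MASCHERONI, HyperParams, SurvivalData
from bayesw.gibbs import (GibbsConfig, GroupLayout, ModelState,
                          PosteriorSamples, gibbs_bsp, gibbs_serial,
                          init_state, update_pi, update_sigma2_G)
from bayesw.simulate import SimDesign, simulate_dataset, simulate_genotypes


@pytest.fixture(scope="module")
def tiny_fit_inputs():
    design = SimDesign(n_individuals=300, n_markers=400, n_causal=8, seed=3)
    data, X, truth = simulate_dataset(design)
    layout = GroupLayout.single_group(X.n_markers, (0.001, 0.01))
    return data, X, layout, truth


class TestGroupLayout:
    def test_groups_partition_markers(self):
        with pytest.raises(ValueError):
            GroupLayout(group_of=np.zeros(10, dtype=int),
                        constants=[np.array([0.01]), np.array([0.01])])

    def test_nonincreasing_constants_rejected(self):
        with pytest.raises(ValueError):
            GroupLayout.single_group(5, (0.01, 0.001))


class TestInitState:
    def test_shape_init_inverts_gumbel_variance(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        state = init_state(data, X, HyperParams(), layout)
        var = float(np.var(data.log_time))
        assert state.alpha == pytest.approx(
            math.sqrt(math.pi**2 / (6 * var)))
        assert state.mu == pytest.approx(float(np.mean(data.log_time)))

    def test_everything_starts_excluded(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        state = init_state(data, X, HyperParams(), layout)
        assert np.all(state.gamma == 0) and np.all(state.beta == 0)
        state.check_consistency()

    def test_variance_split_across_markers_and_groups(self, tiny_fit_inputs):
        data, X, _, _ = tiny_fit_inputs
        layout2 = GroupLayout(
            group_of=np.arange(X.n_markers) % 2,
            constants=[np.array([0.01]), np.array([0.01])])
        state = init_state(data, X, HyperParams(), layout2)
        var = float(np.var(data.log_time))
        assert state.sigma2_g.sum() == pytest.approx(var / X.n_markers)

    def test_initial_residual_is_log_time_minus_mean(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        state = init_state(data, X, HyperParams(), layout)
        assert np.allclose(state.resid.true_eps,
                           data.log_time - data.log_time.mean())


class _RecordingRng:
    """Captures the gamma-draw shape; returns the mean of the distribution."""

    def __init__(self):
        self.shapes = []

    def gamma(self, shape):
        self.shapes.append(shape)
        return shape  # => inverse-gamma draw equals scale/shape


def _state_with(gamma, beta, layout, data, X):
    st = init_state(data, X, HyperParams(), layout)
    st.gamma = np.asarray(gamma, dtype=np.int64)
    st.beta = np.asarray(beta, float)
    return st


class TestSigma2GUpdate:
    def test_empty_model_draws_from_prior(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        st = init_state(data, X, HyperParams(), layout)
        rng = np.random.default_rng(0)
        draws = np.array([update_sigma2_G(st, layout,
                                          HyperParams(alpha_sigma=3.0,
                                                      beta_sigma=2.0),
                                          rng)[0] for _ in range(4000)])
        ref = stats.invgamma(3.0, scale=2.0)
        assert stats.kstest(draws, ref.cdf).pvalue > 0.001

    def test_shape_with_three_included_markers(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        gamma = np.zeros(X.n_markers, dtype=int)
        beta = np.zeros(X.n_markers)
        gamma[:3] = [1, 2, 1]
        beta[:3] = [0.1, -0.2, 0.05]
        st = _state_with(gamma, beta, layout, data, X)
        rec = _RecordingRng()
        update_sigma2_G(st, layout, HyperParams(alpha_sigma=1.0), rec)
        assert rec.shapes[0] == pytest.approx(2.5)

    def test_scale_tracks_realized_genetic_variance(self, tiny_fit_inputs):
        # scale = beta_sigma + (m/2) sum beta^2 => the inverse-gamma mean
        # sits at ~sum(beta^2), the group's realized genetic variance
        data, X, layout, _ = tiny_fit_inputs
        gamma = np.zeros(X.n_markers, dtype=int)
        beta = np.zeros(X.n_markers)
        gamma[:3] = [1, 1, 2]
        beta[:3] = [0.1, 0.2, 0.3]
        st = _state_with(gamma, beta, layout, data, X)
        hyper = HyperParams(alpha_sigma=1.0, beta_sigma=1e-4)
        rec = _RecordingRng()
        val = update_sigma2_G(st, layout, hyper, rec)[0]
        expected_scale = 1e-4 + 0.5 * 3 * (0.01 + 0.04 + 0.09)
        assert val == pytest.approx(expected_scale / 2.5)

    def test_prior_preserved_under_successive_conditionals(self):
        # Geweke-style: the update is the exact conjugate for effects drawn
        # as N(0, sigma2_G/|gamma^k|); alternating that draw with the
        # variance update must keep sigma2_G marginally at its prior.
        rng = np.random.default_rng(11)
        m = 4
        layout = GroupLayout.single_group(m, (0.01,))
        data = SurvivalData.from_times(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                                       np.ones(5, int))
        X = simulate_genotypes(SimDesign(n_individuals=5, n_markers=m,
                                         n_causal=1, seed=1))
        hyper = HyperParams(alpha_sigma=4.0, beta_sigma=3.0)
        st = init_state(data, X, hyper, layout)
        st.gamma = np.ones(m, dtype=np.int64)
        s2 = 3.0 / rng.gamma(4.0)
        draws = []
        for _ in range(6000):
            st.beta = rng.normal(0.0, math.sqrt(s2 / m), size=m)
            s2 = update_sigma2_G(st, layout, hyper, rng)[0]
            draws.append(s2)
        draws = np.array(draws[500:])
        prior_mean = 3.0 / (4.0 - 1.0)
        se = draws.std() / math.sqrt(len(draws) / 10)  # crude ESS deflation
        assert abs(draws.mean() - prior_mean) < 4 * se


class TestPiUpdate:
    def test_dirichlet_counts_moments(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        gamma = np.zeros(X.n_markers, dtype=int)
        gamma[:5] = [1, 1, 1, 2, 2]
        st = _state_with(gamma, np.zeros(X.n_markers), layout, data, X)
        rng = np.random.default_rng(1)
        draws = np.array([update_pi(st, layout, HyperParams(), rng)[0]
                          for _ in range(10_000)])
        counts = np.array([X.n_markers - 5, 3, 2])
        expect = (1.0 + counts) / (3.0 + X.n_markers)
        se = draws.std(axis=0) / 100.0
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-4)

    def test_empty_occupancy_reduces_to_prior(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        st = init_state(data, X, HyperParams(), layout)
        rng = np.random.default_rng(2)
        draws = np.array([update_pi(st, layout, HyperParams(), rng)[0]
                          for _ in range(5000)])
        # occupancy is all-spike at init: Dirichlet(1 + M, 1, 1)
        expect = np.array([1.0 + X.n_markers, 1.0, 1.0])
        expect = expect / expect.sum()
        assert np.abs(draws.mean(axis=0) - expect).max() < 3e-3


class TestSerialSampler:
    def test_fixed_seed_bit_identical(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(iterations=60, burn_in=20, thinning=2, seed=9)
        a = gibbs_serial(data, X, HyperParams(), layout, cfg)
        b = gibbs_serial(data, X, HyperParams(), layout, cfg)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta_value, b.beta_value)
        assert np.array_equal(a.pi, b.pi)

    def test_beta_gamma_consistency_in_final_state(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(iterations=40, burn_in=10, thinning=1, seed=4,
                          keep_final_state=True)
        s = gibbs_serial(data, X, HyperParams(), layout, cfg)
        s.final_state.check_consistency()

    def test_retained_count_contract(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(iterations=55, burn_in=15, thinning=4, seed=1)
        s = gibbs_serial(data, X, HyperParams(), layout, cfg)
        assert s.n_samples == len(range(15, 55, 4)) == 10

    def test_null_phenotype_keeps_heritability_near_zero(self):
        # pure-noise calibration: no signal => posterior h2 stays tiny
        from bayesw.analysis import heritability_log_scale

        rng = np.random.default_rng(77)
        X = simulate_genotypes(SimDesign(n_individuals=800, n_markers=1000,
                                         n_causal=1, seed=21))
        log_y = 3.6 + 0.2 * (-np.log(rng.standard_exponential(800))
                             * -1.0 - EULER_MASCHERONI) / (math.pi / math.sqrt(6))
        data = SurvivalData(log_time=log_y, failure=np.ones(800, dtype=int),
                            trunc_age=np.zeros(800),
                            covariates=np.zeros((800, 0)))
        layout = GroupLayout.single_group(1000, (0.001, 0.01))
        cfg = GibbsConfig(iterations=400, burn_in=200, thinning=5, seed=2)
        s = gibbs_serial(data, X, HyperParams(), layout, cfg)
        assert heritability_log_scale(s).mean < 0.05


class TestCovariateEffects:
    def test_delta_recovers_generative_coefficient(self):
        design = SimDesign(n_individuals=600, n_markers=120, n_causal=4,
                           seed=23)
        data, X, _ = simulate_dataset(design)
        rng = np.random.default_rng(2)
        z = rng.standard_normal((600, 1))
        log_y = data.log_time + 0.15 * z[:, 0]
        data_c = SurvivalData(log_time=log_y, failure=data.failure,
                              trunc_age=np.zeros(600), covariates=z)
        layout = GroupLayout.single_group(120, (0.001, 0.01))
        cfg = GibbsConfig(iterations=300, burn_in=100, thinning=2, seed=8)
        s = gibbs_serial(data_c, X, HyperParams(), layout, cfg)
        assert s.delta.shape[1] == 1
        assert abs(s.delta.mean() - 0.15) < 0.04


class TestLeftTruncation:
    def test_truncated_fit_runs_and_residuals_consistent(self):
        # entry ages on a third of the sample; the chain must run and keep
        # the truncation part of the residual state coherent
        design = SimDesign(n_individuals=250, n_markers=150, n_causal=5,
                           seed=19)
        data, X, _ = simulate_dataset(design)
        rng = np.random.default_rng(1)
        times = np.exp(data.log_time)
        trunc = np.where(rng.random(250) < 0.33,
                         times * rng.uniform(0.1, 0.6, 250), 0.0)
        data_t = SurvivalData(log_time=data.log_time, failure=data.failure,
                              trunc_age=trunc,
                              covariates=np.zeros((250, 0)))
        layout = GroupLayout.single_group(150, (0.001, 0.01))
        cfg = GibbsConfig(iterations=60, burn_in=20, thinning=2, seed=3,
                          keep_final_state=True, rebuild_every=0)
        s = gibbs_serial(data_t, X, HyperParams(), layout, cfg)
        st = s.final_state
        dense_eps = data.log_time - st.mu - X.dot_beta(st.beta)
        assert np.abs(st.resid.true_eps - dense_eps).max() < 1e-8
        # exp(u) stays exactly zero where untruncated, positive elsewhere
        assert np.all((st.resid.true_wu > 0) == (trunc > 0))


class TestBspSampler:
    def test_residual_consistent_with_dense_rebuild(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(iterations=30, burn_in=10, thinning=1, seed=6,
                          workers=2, sync_rate=5, keep_final_state=True,
                          rebuild_every=0)
        s = gibbs_bsp(data, X, HyperParams(), layout, cfg)
        st = s.final_state
        dense_eps = (data.log_time - st.mu - X.dot_beta(st.beta))
        assert np.abs(st.resid.true_eps - dense_eps).max() < 1e-8

    def test_single_worker_unit_rate_equals_serial_bitwise(
            self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(iterations=50, burn_in=10, thinning=2, seed=13)
        a = gibbs_serial(data, X, HyperParams(), layout, cfg)
        cfg_b = GibbsConfig(iterations=50, burn_in=10, thinning=2, seed=13,
                            workers=1, sync_rate=1)
        b = gibbs_bsp(data, X, HyperParams(), layout, cfg_b)
        for field in ("alpha", "mu", "sigma2_g", "beta_value", "beta_marker"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_invalid_worker_count_rejected(self, tiny_fit_inputs):
        data, X, layout, _ = tiny_fit_inputs
        cfg = GibbsConfig(workers=0)
        with pytest.raises(ValueError):
            gibbs_bsp(data, X, HyperParams(), layout, cfg)


class TestOccupancyAgainstEnumeration:
    """Reduced Gibbs over (gamma, beta) vs brute-force enumeration.

    Everything else (mu, alpha, sigma2_G, pi) is held fixed so the
    stationary occupancy law is enumerable: for each of the 2^5 inclusion
    configurations the marginal likelihood is a low-dimensional integral
    estimated by quasi-Monte-Carlo over the effect prior.
    """

    M, N, C, S2G, ALPHA, MU = 5, 30, 0.1, 0.05, 3.0, 1.0

    def _setup(self):
        rng = np.random.default_rng(42)
        X = simulate_genotypes(SimDesign(n_individuals=self.N,
                                         n_markers=self.M, n_causal=1,
                                         seed=8))
        xs = X.toarray()
        beta_true = np.array([0.25, -0.2, 0.0, 0.0, 0.0])
        err = np.log(rng.standard_exponential(self.N)) + EULER_MASCHERONI
        log_y = self.MU + xs @ beta_true + err / self.ALPHA
        data = SurvivalData(log_time=log_y,
                            failure=np.ones(self.N, dtype=int),
                            trunc_age=np.zeros(self.N),
                            covariates=np.zeros((self.N, 0)))
        return data, X, xs

    def _loglik(self, data, xs, beta):
        lp = self.MU + xs @ beta
        v = self.ALPHA * (data.log_time - lp) - EULER_MASCHERONI
        return (self.N * math.log(self.ALPHA) - self.N * EULER_MASCHERONI
                + (self.ALPHA - 1) * data.log_time.sum()
                - self.ALPHA * lp.sum() - np.exp(v).sum())

    def _brute_occupancy(self, data, xs, pi0):
        from itertools import product

        slab_var = self.C * self.S2G
        sob = stats.qmc.Sobol(d=self.M, seed=1).random(2**12)
        z = stats.norm.ppf(np.clip(sob, 1e-9, 1 - 1e-9)) * math.sqrt(slab_var)
        log_post = {}
        for cfgr in product([0, 1], repeat=self.M):
            sel = np.array(cfgr, dtype=bool)
            if sel.any():
                liks = np.array([
                    self._loglik(data, xs,
                                 np.where(sel, z[i], 0.0))
                    for i in range(z.shape[0])])
                shift = liks.max()
                log_ml = shift + math.log(np.mean(np.exp(liks - shift)))
            else:
                log_ml = self._loglik(data, xs, np.zeros(self.M))
            prior = (np.log(1 - pi0) * sel.sum()
                     + np.log(pi0) * (self.M - sel.sum()))
            log_post[cfgr] = log_ml + prior
        keys = list(log_post)
        vals = np.array([log_post[k] for k in keys])
        vals = np.exp(vals - vals.max())
        vals /= vals.sum()
        occ = np.zeros(self.M)
        for k, v in zip(keys, vals):
            occ += np.array(k) * v
        return occ

    def test_long_run_occupancy_matches_enumeration(self):
        from bayesw.core import WeibullParams, log_post_beta_j
        from bayesw.samplers import (ars_sample, hermite_rule,
                                     inclusion_probabilities,
                                     log_marginal_slab)

        data, X, xs = self._setup()
        pi0 = 0.6
        rng = np.random.default_rng(7)
        rule = hermite_rule(25)
        beta = np.zeros(self.M)
        occ = np.zeros(self.M)
        sweeps = 4000
        d_x = xs.T @ data.failure.astype(float)
        hyper = HyperParams()
        for sweep in range(sweeps):
            for j in range(self.M):
                beta_mj = beta.copy()
                beta_mj[j] = 0.0
                lp = self.MU + xs @ beta_mj
                v = self.ALPHA * (data.log_time - lp) - EULER_MASCHERONI
                wdiff = np.exp(v)
                logm = log_marginal_slab(xs[:, j], wdiff, d_x[j], self.ALPHA,
                                         self.C, self.S2G, rule)
                p = inclusion_probabilities(np.array([pi0, 1 - pi0]),
                                            np.array([logm]))
                if rng.random() < p[1]:
                    params = WeibullParams(mu=self.MU, alpha=self.ALPHA,
                                           beta=beta_mj)
                    target = log_post_beta_j(data, params, hyper, xs[:, j],
                                             j, 1, self.C, self.S2G, xs)
                    half = math.sqrt(self.C * self.S2G)
                    beta[j] = ars_sample(target, [-half, 0.0, half],
                                         (beta[j] - 2 * half,
                                          beta[j] + 2 * half), rng)
                else:
                    beta[j] = 0.0
                if sweep >= 500:
                    occ[j] += beta[j] != 0.0
        occ /= (sweeps - 500)
        ref = self._brute_occupancy(data, xs, pi0)
        assert np.abs(occ - ref).max() < 0.05
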