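import math

import numpy as np
import pytest
from scipy import stats

from switchtissue.inference import (
    HierarchySpec,
    MCMCConfig,
    PriorSpec,
    birth_death_logratio,
    hierarchical_sweep,
    recursive_residuals,
    rjmcmc_sample,
)
from switchtissue.lna import dense_kalman_loglik, lna_loglik, stationary_moments
from switchtissue.types import KineticParams, TranscriptionProfile

from conftest import make_ssa_trace


class TestLNALikelihood:
    def test_single_observation_closed_form(self, kp):
        beta = 8.0
        prof = TranscriptionProfile(np.empty(0), np.array([beta]))
        _, m2, _, _, v22 = stationary_moments(beta, kp)
        S = kp.kappa**2 * v22 + kp.sigma2
        y = 200.0
        expected = -0.5 * (math.log(2 * math.pi * S) + (y - kp.kappa * m2) ** 2 / S)
        got = lna_loglik(np.array([0.0]), np.array([y]), prof, kp)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_reference_filter(self, kp, grid_46h):
        rng = np.random.default_rng(0)
        for _ in range(2):
            k = int(rng.integers(0, 4))
            sw = np.sort(rng.uniform(2, 44, k))
            rates = rng.uniform(1, 30, k + 1)
            prof = TranscriptionProfile(sw, rates)
            y = make_ssa_trace(prof, kp, grid_46h, rng)
            fast = lna_loglik(grid_46h, y, prof, kp)
            dense = dense_kalman_loglik(grid_46h, y, prof, kp, dt=2e-3)
            assert fast == pytest.approx(dense, abs=1e-4)

    def test_phantom_switch_is_invisible(self, kp, grid_46h):
        rng = np.random.default_rng(1)
        prof = TranscriptionProfile(np.empty(0), np.array([10.0]))
        y = make_ssa_trace(prof, kp, grid_46h, rng)
        # build an equal-rate "switch" below the validation layer
        phantom = TranscriptionProfile.__new__(TranscriptionProfile)
        phantom.switch_times = np.array([20.0])
        phantom.rates = np.array([10.0, 10.0])
        phantom.weight = 1.0
        assert lna_loglik(grid_46h, y, prof, kp) == pytest.approx(
            lna_loglik(grid_46h, y, phantom, kp), abs=1e-9)

    def test_doubling_sigma2_costs_the_normalisation(self, grid_46h):
        # dominated measurement noise; data pinned at the predictive mean
        kp1 = KineticParams(sigma2=1e6)
        kp2 = KineticParams(sigma2=2e6)
        prof = TranscriptionProfile(np.empty(0), np.array([5.0]))
        _, m2, *_ = stationary_moments(5.0, kp1)
        y = np.full(len(grid_46h), kp1.kappa * m2)
        d = lna_loglik(grid_46h, y, prof, kp1) - lna_loglik(grid_46h, y, prof, kp2)
        assert d == pytest.approx(0.5 * len(y) * math.log(2.0), rel=1e-2)

    def test_zero_noise_mismatch_returns_neg_inf(self, grid_46h):
        kp0 = KineticParams(sigma2=0.0)
        prof = TranscriptionProfile(np.empty(0), np.array([0.0]))
        y = np.full(len(grid_46h), 50.0)   # impossible under a silent gene
        assert lna_loglik(grid_46h, y, prof, kp0) == -math.inf


class TestRJMCMC:
    def test_birth_death_proposal_ratios_cancel(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = int(rng.integers(0, 5))
            rates = rng.uniform(0.5, 30, k + 1)
            j = int(rng.integers(k + 1))
            u = float(rng.normal(0, 0.5))
            birth, death = birth_death_logratio(rates, j, u, 0.5, (0.0, 46.0), k)
            assert birth + death == pytest.approx(0.0, abs=1e-10)

    def test_zero_retained_samples_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            MCMCConfig(n_iter=100, burn_in=100, thin=5)

    def test_prior_only_chain_reproduces_k_prior(self, grid_46h):
        priors = PriorSpec()
        s = rjmcmc_sample(grid_46h, np.zeros_like(grid_46h), priors,
                          MCMCConfig(n_iter=150_000, burn_in=5_000, thin=50),
                          rng=1, use_likelihood=False)
        p = priors.k_geom_p
        probs = np.array([(1 - p) ** k for k in range(priors.k_max + 1)])
        probs /= probs.sum()
        obs = np.bincount(s.k, minlength=priors.k_max + 1).astype(float)
        obs_m = np.concatenate([obs[:5], [obs[5:].sum()]])
        exp_m = np.concatenate([probs[:5], [probs[5:].sum()]]) * len(s.k)
        assert stats.chisquare(obs_m, exp_m).pvalue > 0.01

    def test_constant_rate_trace_prefers_no_switch(self, kp, grid_46h):
        rng = np.random.default_rng(3)
        prof = TranscriptionProfile(np.empty(0), np.array([10.0]))
        y = make_ssa_trace(prof, kp, grid_46h, rng)
        s = rjmcmc_sample(grid_46h, y, PriorSpec(),
                          MCMCConfig(n_iter=8_000, burn_in=2_000, thin=5), rng=4)
        assert np.mean(s.k == 0) > 0.5

    def test_single_switch_recovery(self, kp, grid_46h):
        rng = np.random.default_rng(5)
        truth_t = 20.7
        prof = TranscriptionProfile(np.array([truth_t]), np.array([5.0, 25.0]))
        y = make_ssa_trace(prof, kp, grid_46h, rng)
        s = rjmcmc_sample(grid_46h, y, PriorSpec(),
                          MCMCConfig(n_iter=12_000, burn_in=3_000, thin=5), rng=6)
        assert s.modal_k() == 1
        assert abs(np.median(s.pooled_switch_times()) - truth_t) <= 1.0
        proposed = sum(v[0] for v in s.ledger.values())
        assert proposed == 12_000                 # ledger counts all proposals


class TestCalibration:
    def test_switch_time_rank_histogram_is_uniform(self, grid_46h):
        """Simulation-based calibration at coarse resolution: over 20 cells
        whose single-switch truths are drawn from the prior, the rank of the
        true switch time within its posterior draws is uniform."""
        priors = PriorSpec()
        rng = np.random.default_rng(77)
        ranks = []
        for _ in range(20):
            s_true = rng.uniform(0.5 + priors.delta_min, 45.5 - priors.delta_min)
            while True:
                b = rng.lognormal(priors.beta_log_mean, priors.beta_log_sd, 2)
                if abs(np.log(b[1] / b[0])) > 0.05:
                    break
            dm = rng.lognormal(priors.dm_log_mean, priors.dm_log_sd)
            dp = rng.lognormal(priors.dp_log_mean, priors.dp_log_sd)
            s2 = stats.invgamma.rvs(priors.sigma2_shape, scale=priors.sigma2_scale,
                                    random_state=rng)
            kp = KineticParams(delta_m=dm, delta_p=dp, alpha=priors.alpha,
                               kappa=priors.kappa, sigma2=s2)
            prof = TranscriptionProfile(np.array([s_true]), b)
            y = make_ssa_trace(prof, kp, grid_46h, rng, noise_sd=np.sqrt(s2))
            s = rjmcmc_sample(grid_46h, y, priors,
                              MCMCConfig(n_iter=10_000, burn_in=3_000, thin=5),
                              rng=int(rng.integers(2**31)))
            draws = s.pooled_switch_times()
            ranks.append(float((draws < s_true).mean()) if len(draws)
                         else float(rng.uniform()))
        assert stats.kstest(np.array(ranks), "uniform").pvalue > 0.01


class TestHierarchy:
    def _chains_with_deltas(self, dms, dps):
        chains = []
        for dm, dp in zip(dms, dps):
            c = rjmcmc_sample(np.arange(0, 5.01, 0.25), np.zeros(21), PriorSpec(),
                              MCMCConfig(n_iter=60, burn_in=10, thin=5),
                              rng=0, use_likelihood=False)
            c.delta_m = np.array([dm])
            c.delta_p = np.array([dp])
            chains.append(c)
        return chains

    def test_identical_cells_shrink_scale(self):
        rng = np.random.default_rng(7)
        same = self._chains_with_deltas([0.7] * 12, [0.35] * 12)
        spread = self._chains_with_deltas(
            [0.3] * 6 + [1.4] * 6, [0.15] * 6 + [0.7] * 6)
        h = HierarchySpec()
        scales_same = [hierarchical_sweep(same, h, rng=i)[0]["dm"][1] for i in range(10)]
        scales_spread = [hierarchical_sweep(spread, h, rng=i)[0]["dm"][1] for i in range(10)]
        assert np.mean(scales_same) < np.mean(scales_spread)
        assert np.mean(scales_same) < 0.3          # near the hyperprior floor

    def test_single_cell_degenerates_with_fixed_prior(self):
        chains = self._chains_with_deltas([0.7], [0.35])
        pop, priors = hierarchical_sweep(chains, HierarchySpec(), rng=0)
        assert priors[0].dm_log_mean == PriorSpec().dm_log_mean


class TestRecursiveResiduals:
    def test_well_specified_model_gives_white_residuals(self, kp, grid_46h):
        rng = np.random.default_rng(8)
        prof = TranscriptionProfile(np.empty(0), np.array([10.0]))
        y = make_ssa_trace(prof, kp, grid_46h, rng)
        s = rjmcmc_sample(grid_46h, y, PriorSpec(),
                          MCMCConfig(n_iter=6_000, burn_in=2_000, thin=5), rng=9)
        diag = recursive_residuals(grid_46h, y, s, kp)
        assert diag.ks_pvalue > 0.01
        assert abs(diag.lag1_acf) < 2 * diag.band

    def test_unmodelled_switch_is_flagged(self, kp, grid_46h):
        rng = np.random.default_rng(10)
        prof = TranscriptionProfile(np.array([20.0]), np.array([3.0, 30.0]))
        y = make_ssa_trace(prof, kp, grid_46h, rng)
        # force a constant-rate fit by restricting the prior to K = 0
        s = rjmcmc_sample(grid_46h, y, PriorSpec(k_max=0),
                          MCMCConfig(n_iter=4_000, burn_in=1_000, thin=5), rng=11)
        diag = recursive_residuals(grid_46h, y, s, kp)
        assert diag.lag1_acf > diag.band           # autocorrelated misfit
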