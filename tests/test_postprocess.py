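import numpy as np
import pytest

from switchtissue.inference import PosteriorSamples
from switchtissue.postprocess import (
    ACTIVE,
    LOW,
    CandidateSwitchSet,
    bootstrap_mannwhitney,
    cell_duration_distribution,
    classify_low_active,
    duration_by_rate_bin,
    enumerate_submodels,
    fit_switch_mixture,
    inter_switch_kde,
    inter_switch_times,
    rate_distribution,
    sample_profile,
    switch_count_summary,
    weighted_quantiles,
)
from switchtissue.types import ProfileSet, TranscriptionProfile

WINDOW = (0.0, 46.0)


def make_samples(draws):
    """Build PosteriorSamples from a list of (switch_times, rates) tuples."""
    sw = [np.asarray(s, float) for s, _ in draws]
    rates = [np.asarray(r, float) for _, r in draws]
    n = len(draws)
    return PosteriorSamples(
        k=np.array([len(s) for s in sw]),
        switch_times=sw,
        rates=rates,
        delta_m=np.full(n, 0.7),
        delta_p=np.full(n, 0.35),
        sigma2=np.full(n, 25.0),
        loglik=np.zeros(n),
        ledger={},
        window=WINDOW,
    )


class TestSwitchMixture:
    def test_no_switch_draws_give_empty_set(self):
        s = make_samples([((), (5.0,))] * 50)
        cands = fit_switch_mixture(s)
        assert len(cands) == 0

    def test_two_well_separated_clusters(self):
        rng = np.random.default_rng(0)
        draws = [((rng.normal(10, 0.5), rng.normal(30, 0.5)), (1.0, 8.0, 2.0))
                 for _ in range(300)]
        cands = fit_switch_mixture(make_samples(draws))
        assert len(cands) == 2
        assert cands.means[0] == pytest.approx(10.0, abs=0.3)
        assert cands.means[1] == pytest.approx(30.0, abs=0.3)

    def test_single_tight_cluster(self):
        rng = np.random.default_rng(1)
        draws = [((rng.normal(15, 0.3),), (1.0, 9.0)) for _ in range(300)]
        cands = fit_switch_mixture(make_samples(draws))
        assert len(cands) == 1
        assert cands.means[0] == pytest.approx(15.0, abs=0.2)


class TestSubmodels:
    def _two_candidate_samples(self, n_each=(50, 50, 50, 50)):
        rng = np.random.default_rng(2)
        draws = []
        draws += [((), (3.0,))] * n_each[0]
        draws += [((rng.normal(10, 0.3),), (1.0, 8.0)) for _ in range(n_each[1])]
        draws += [((rng.normal(30, 0.3),), (8.0, 2.0)) for _ in range(n_each[2])]
        draws += [((rng.normal(10, 0.3), rng.normal(30, 0.3)), (1.0, 8.0, 2.0))
                  for _ in range(n_each[3])]
        return make_samples(draws)

    def test_two_candidates_enumerate_four_profiles(self):
        s = self._two_candidate_samples()
        cands = fit_switch_mixture(s)
        ps = enumerate_submodels(s, cands, cell_id="c")
        assert len(ps.profiles) == 4
        ks = sorted(p.n_switches for p in ps.profiles)
        assert ks == [0, 1, 1, 2]
        assert sum(p.weight for p in ps.profiles) == pytest.approx(1.0)

    def test_weights_match_brute_force_counts(self):
        s = self._two_candidate_samples(n_each=(10, 20, 30, 40))
        cands = fit_switch_mixture(s)
        ps = enumerate_submodels(s, cands, cell_id="c")
        w = {p.n_switches if p.n_switches != 1 else (1, round(p.switch_times[0]))
             : p.weight for p in ps.profiles}
        assert w[0] == pytest.approx(0.10, abs=0.02)
        assert w[(1, 10)] == pytest.approx(0.20, abs=0.02)
        assert w[(1, 30)] == pytest.approx(0.30, abs=0.02)
        assert w[2] == pytest.approx(0.40, abs=0.02)

    def test_unanimous_draws_put_weight_one(self):
        rng = np.random.default_rng(3)
        draws = [((rng.normal(10, 0.3), rng.normal(30, 0.3)), (1.0, 8.0, 2.0))
                 for _ in range(100)]
        s = make_samples(draws)
        ps = enumerate_submodels(s, fit_switch_mixture(s), cell_id="c")
        assert len(ps.profiles) == 1
        assert ps.profiles[0].weight == 1.0


class TestProfileSampling:
    def test_degenerate_and_multinomial(self):
        p0 = TranscriptionProfile(np.empty(0), np.array([2.0]), 1.0)
        ps = ProfileSet(cell_id="c", profiles=[p0])
        rng = np.random.default_rng(4)
        assert sample_profile(ps, rng) is p0
        pa = TranscriptionProfile(np.empty(0), np.array([2.0]), 0.7)
        pb = TranscriptionProfile(np.array([10.0]), np.array([1.0, 5.0]), 0.3)
        ps = ProfileSet(cell_id="c", profiles=[pa, pb])
        n = 10_000
        hits = sum(sample_profile(ps, rng) is pa for _ in range(n))
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(hits / n - 0.7) < 3 * se


class TestWeightedSummaries:
    def _four_profile_cell(self, weights=(0.25, 0.25, 0.25, 0.25)):
        return ProfileSet(cell_id="c", profiles=[
            TranscriptionProfile(np.empty(0), np.array([3.0]), weights[0]),
            TranscriptionProfile(np.array([10.0]), np.array([1.0, 8.0]), weights[1]),
            TranscriptionProfile(np.array([30.0]), np.array([8.0, 2.0]), weights[2]),
            TranscriptionProfile(np.array([10.0, 30.0]), np.array([1.0, 8.0, 2.0]),
                                 weights[3]),
        ])

    def test_switch_count_histogram(self):
        hist = switch_count_summary([self._four_profile_cell()])
        assert hist[0] == pytest.approx(0.25)
        assert hist[1] == pytest.approx(0.50)
        assert hist[2] == pytest.approx(0.25)

    def test_rate_distribution_point_mass(self):
        cell = ProfileSet(cell_id="c", profiles=[
            TranscriptionProfile(np.empty(0), np.array([7.0]), 1.0)])
        grid, dens = rate_distribution([cell], WINDOW, mode="density")
        assert grid[np.argmax(dens)] == pytest.approx(7.0, abs=0.2)
        # density integrates to ~1
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_weighted_cdf_matches_ecdf(self):
        cell = self._four_profile_cell()
        grid, cdf = rate_distribution([cell], WINDOW, mode="cdf",
                                      bandwidth=1e-3)
        # with a negligible bandwidth the smoothed CDF equals the weighted
        # empirical CDF of (rate, weight x duration)
        from switchtissue.postprocess import _weighted_rate_durations
        x, w = _weighted_rate_durations([cell], WINDOW)
        wn = w / w.sum()
        ecdf = [(wn[x <= g + 1e-9]).sum() for g in grid]
        np.testing.assert_allclose(cdf, ecdf, atol=0.01)

    def test_duration_binning_and_censoring(self):
        cell = ProfileSet(cell_id="c", profiles=[
            TranscriptionProfile(np.empty(0), np.array([5.0]), 1.0)])
        df = duration_by_rate_bin([cell], WINDOW, binning="q75_split", rng=0)
        assert len(df) == 1
        assert df.loc[0, "duration_h"] == pytest.approx(46.0)
        assert bool(df.loc[0, "censored"])

    def test_decile_edges_give_equal_occupancy(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 20, 5000)
        w = np.ones_like(x)
        edges = weighted_quantiles(x, w, np.arange(1, 10) / 10)
        counts = np.histogram(x, bins=np.concatenate([[0], edges, [20]]))[0]
        assert counts.std() / counts.mean() < 0.1


class TestLowActive:
    @pytest.mark.parametrize("rates, expected", [
        ([5.0, 1.0, 6.0], [ACTIVE, LOW, ACTIVE]),
        ([1.0, 5.0, 2.0], [ACTIVE, ACTIVE, ACTIVE]),
        ([1.0, 2.0, 3.0], [ACTIVE, ACTIVE, ACTIVE]),
    ])
    def test_definition(self, rates, expected):
        k = len(rates) - 1
        prof = TranscriptionProfile(np.linspace(10, 30, k), np.array(rates))
        assert classify_low_active(prof) == expected

    def test_no_switch_cells_excluded(self):
        with pytest.raises(ValueError):
            classify_low_active(TranscriptionProfile(np.empty(0), np.array([2.0])))


class TestInterSwitch:
    def test_complete_intervals_only(self):
        cells = [ProfileSet(cell_id="a", profiles=[
            TranscriptionProfile(np.array([10.0, 30.0]), np.array([1.0, 8.0, 2.0]), 0.5),
            TranscriptionProfile(np.array([12.0]), np.array([1.0, 8.0]), 0.5),
        ])]
        d, w = inter_switch_times(cells)
        np.testing.assert_allclose(d, [20.0])       # K<=1 contributes nothing
        np.testing.assert_allclose(w, [0.5])

    def test_kde_total_weight(self):
        cells = [ProfileSet(cell_id="a", profiles=[
            TranscriptionProfile(np.array([10.0, 30.0]), np.array([1.0, 8.0, 2.0]), 0.3),
            TranscriptionProfile(np.empty(0), np.array([4.0]), 0.7),
        ])]
        grid, dens, total = inter_switch_kde(cells)
        assert total == pytest.approx(0.3)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.05)


class TestBootstrapMWU:
    def test_null_calibration_and_power(self):
        rng = np.random.default_rng(6)
        ga = [(rng.exponential(10, 8), np.ones(8)) for _ in range(25)]
        gb = [(rng.exponential(10, 8), np.ones(8)) for _ in range(25)]
        null = bootstrap_mannwhitney(ga, gb, n_boot=300, rng=1)
        assert null["frac_below_line"] < 0.2 and not null["significant"]
        gc = [(rng.exponential(2, 8), np.ones(8)) for _ in range(25)]
        power = bootstrap_mannwhitney(ga, gc, n_boot=300, rng=2)
        assert power["frac_below_line"] >= 0.9 and power["significant"]

    def test_single_bootstrap_degenerates(self):
        ga = [(np.array([1.0, 2.0]), np.array([0.5, 0.5]))] * 4
        gb = [(np.array([5.0, 6.0]), np.array([0.5, 0.5]))] * 4
        out = bootstrap_mannwhitney(ga, gb, n_boot=1, rng=0)
        assert len(out["pvalues"]) == 1

    def test_low_active_duration_distributions(self):
        cell = ProfileSet(cell_id="c", profiles=[
            TranscriptionProfile(np.array([10.0, 30.0]), np.array([5.0, 1.0, 6.0]), 1.0)])
        d_low, w_low = cell_duration_distribution(cell, WINDOW, label=LOW)
        np.testing.assert_allclose(d_low, [20.0])
        d_act, _ = cell_duration_distribution(cell, WINDOW, label=ACTIVE)
        assert sorted(d_act) == [10.0, 16.0]
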