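import dataclasses

import networkx as nx
import numpy as np
import pytest

from switchtissue.spatial import (
    connectivity_classes,
    connectivity_correlation,
    correlation_vs_distance,
    make_distance_bins,
    pair_correlation,
    permutation_null,
    ripley_k,
    switch_synchrony,
)
from switchtissue.synthetic import TissueConfig, place_cells, simulate_tissue
from switchtissue.types import CellTrack, ProfileSet, TranscriptionProfile, TrackSet


def _trackset_from(traces, positions):
    n_t = traces.shape[1]
    t = 0.25 * np.arange(n_t)
    tracks = [
        CellTrack(cell_id=f"c{i}", times=t, fluor=traces[i][:, None],
                  centroids=np.tile(positions[i], (n_t, 1)))
        for i in range(len(traces))
    ]
    return TrackSet(tracks=tracks, zero_background=True)


class TestRipley:
    def test_theoretical_k_is_pi_r_squared(self):
        pts = place_cells(50, (200, 200), "CSR", rng=np.random.default_rng(0))
        r = np.linspace(1, 40, 10)
        res = ripley_k(pts, (200, 200), r, n_sim=9, rng=0)
        np.testing.assert_allclose(res.k_theo, np.pi * r**2)

    def test_csr_inside_envelope(self):
        pts = place_cells(200, (400, 400), "CSR", rng=np.random.default_rng(1))
        res = ripley_k(pts, (400, 400), np.linspace(2, 80, 30), n_sim=99, rng=1)
        assert res.fraction_inside() >= 0.95

    def test_hard_core_breaches_lower_envelope(self):
        pts = place_cells(200, (400, 400), "hard-core", min_sep=10,
                          rng=np.random.default_rng(2))
        res = ripley_k(pts, (400, 400), np.array([4.0, 8.0, 30.0, 60.0]),
                       n_sim=99, rng=2)
        assert (res.k_obs[:2] < res.k_lo[:2]).all()     # r below the core
        assert res.k_obs[3] >= res.k_lo[3]              # random at large r

    def test_translation_correction_unbiased_mean(self):
        # under CSR the translation-corrected estimator is exactly unbiased
        rng = np.random.default_rng(3)
        r = np.array([10.0, 25.0])
        ks = np.array([
            ripley_k(place_cells(100, (200, 200), "CSR", rng=rng), (200, 200),
                     r, n_sim=1, rng=0).k_obs
            for _ in range(80)
        ])
        se = ks.std(axis=0) / np.sqrt(len(ks))
        assert np.all(np.abs(ks.mean(axis=0) - np.pi * r**2) < 3.5 * se)


class TestPairCorrelation:
    def test_identity_orthogonality_and_oracle(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pair_correlation(x, x) == pytest.approx(1.0)
        assert pair_correlation(x, y) == pytest.approx(0.0)
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 50))
        assert pair_correlation(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1],
                                                       abs=1e-12)

    def test_literal_mode_is_mean_cross_product(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        assert pair_correlation(a, b, standardize=False) == pytest.approx(
            np.mean(a * b))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pair_correlation(np.ones(5), np.arange(5.0))


class TestCorrelationVsDistance:
    def test_identical_traces_saturate(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=60)
        traces = np.tile(base, (12, 1))
        pos = place_cells(12, (60, 60), "CSR", rng=rng)
        res = correlation_vs_distance(_trackset_from(traces, pos),
                                      make_distance_bins(60), rng=0)
        t = res.table[res.table.n_pairs > 0]
        np.testing.assert_allclose(t["median"], 1.0)
        np.testing.assert_allclose(t["boot_hi"] - t["boot_lo"], 0.0, atol=1e-12)

    def test_single_pair_bin_degenerate_bootstrap(self):
        rng = np.random.default_rng(6)
        traces = rng.normal(size=(2, 60))
        pos = np.array([[0.0, 0.0], [12.0, 0.0]])
        res = correlation_vs_distance(_trackset_from(traces, pos),
                                      make_distance_bins(20), rng=0)
        row = res.table[res.table.n_pairs == 1].iloc[0]
        assert row["boot_lo"] == row["median"] == row["boot_hi"]


class TestPermutationNull:
    def test_unstructured_traces_no_significance(self):
        rng = np.random.default_rng(7)
        traces = rng.normal(size=(40, 80))
        pos = place_cells(40, (120, 120), "CSR", rng=rng)
        res = permutation_null(_trackset_from(traces, pos),
                               make_distance_bins(60), n_perm=499, alpha=0.01, rng=1)
        assert not res.table["significant"].any()
        assert res.significant_range_um == 0.0

    def test_self_null_property(self):
        # applying the analysis to already-permuted data is itself null
        rng = np.random.default_rng(8)
        traces = rng.normal(size=(40, 80))
        perm = rng.permutation(40)
        pos = place_cells(40, (120, 120), "CSR", rng=rng)
        res = permutation_null(_trackset_from(traces[perm], pos),
                               make_distance_bins(60), n_perm=499, alpha=0.01, rng=2)
        assert not res.table["significant"].any()


class TestConnectivity:
    def test_all_unconnected_below_threshold(self):
        pos = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        df, _ = connectivity_classes(pos, threshold=10.0)
        assert (df["pair_class"] == "unconnected").all()

    def test_transitive_indirect_chain(self):
        d = 10.0
        pos = np.array([[0.0, 0.0], [0.9 * d, 0.0], [1.8 * d, 0.0]])
        df, _ = connectivity_classes(pos, threshold=d)
        by = {tuple(sorted((int(r.i), int(r.j)))): r.pair_class
              for r in df.itertuples()}
        assert by[(0, 1)] == "direct" and by[(1, 2)] == "direct"
        assert by[(0, 2)] == "indirect"           # 1.8 D apart, same component

    def test_components_match_networkx_oracle(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 100, (50, 2))
        for D in (8.0, 15.0, 30.0):
            df, comp = connectivity_classes(pos, D)
            g = nx.Graph()
            g.add_nodes_from(range(50))
            sub = df[df.pair_class == "direct"]
            g.add_edges_from(zip(sub.i, sub.j))
            for cc in nx.connected_components(g):
                assert len({comp[i] for i in cc}) == 1
            # classes partition all pairs
            assert len(df) == 50 * 49 // 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        pos = rng.uniform(0, 100, (30, 2))
        df1, _ = connectivity_classes(pos, 10.0)
        df2, _ = connectivity_classes(pos, 25.0)
        direct1 = set(map(tuple, df1[df1.pair_class == "direct"][["i", "j"]].to_numpy()))
        conn2 = set(map(tuple, df2[df2.pair_class != "unconnected"][["i", "j"]].to_numpy()))
        assert direct1 <= conn2

    def test_connectivity_correlation_runs(self):
        cfg = TissueConfig(n_cells=40, field_size=(200.0, 200.0))
        ts, _ = simulate_tissue(cfg, 11)
        out = connectivity_correlation(ts, np.array([15.0, 30.0]), rng=0)
        assert len(out) == 2
        for res in out:
            assert res.summaries["n_pairs"].sum() == 40 * 39 // 2


class TestSynchrony:
    def _cells(self, profiles):
        return [ProfileSet(cell_id=f"c{i}", profiles=[p]) for i, p in enumerate(profiles)]

    def test_simultaneous_switches_give_zero_intervals(self):
        p = TranscriptionProfile(np.array([10.0]), np.array([1.0, 5.0]))
        cells = self._cells([p, dataclasses.replace(p)])
        pos = np.array([[0.0, 0.0], [10.0, 0.0]])
        res = switch_synchrony(cells, pos, rng=0, n_resample=1)
        assert (res.records["dt_h"] == 0.0).all()
        assert res.records["same_direction"].all()

    def test_no_switch_cells_contribute_nothing(self):
        p0 = TranscriptionProfile(np.empty(0), np.array([2.0]))
        p1 = TranscriptionProfile(np.array([10.0]), np.array([1.0, 5.0]))
        cells = self._cells([p0, p1, dataclasses.replace(p1)])
        pos = np.array([[0.0, 0.0], [10.0, 0.0], [40.0, 0.0]])
        res = switch_synchrony(cells, pos, rng=0, n_resample=1)
        assert len(res.records) == 1               # only the (1, 2) pair

    def test_every_cross_pair_classified_once(self):
        cfg = TissueConfig(n_cells=25, field_size=(160.0, 160.0))
        _, truth = simulate_tissue(cfg, 12)
        cells = [ProfileSet(cell_id=f"c{i}",
                            profiles=[dataclasses.replace(p, weight=1.0)])
                 for i, p in enumerate(truth.profiles)]
        res = switch_synchrony(cells, truth.positions, rng=0, n_resample=1)
        counts = [p.n_switches for p in truth.profiles]
        total = sum(counts) ** 2 - sum(c * c for c in counts)
        assert len(res.records) == total // 2
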