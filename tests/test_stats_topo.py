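"""t statistics, rank correlation and the cluster permutation test."""

import numpy as np
import pytest

from somnotype.io_formats import AdjacencyGraph
from somnotype.stats_topo import (cluster_mean, critical_t, snpm_cluster_test,
                                  spearman_corr, t_from_summary, unpaired_t)
from somnotype.synthetic_data import make_montage
from somnotype.io_formats import build_adjacency


class TestUnpairedT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = unpaired_t(a, a)
        assert t == 0 and p == 1 and df == 4

    def test_matches_summary_variant_for_equal_n(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 16), rng.normal(0.5, 1, 16)
        t1, _, _ = unpaired_t(a, b)
        t2, _, _ = t_from_summary(a.mean(), a.std(ddof=1) / 4, 16,
                                  b.mean(), b.std(ddof=1) / 4, 16)
        # pooled vs Welch coincide in form for equal n
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_constant_groups_with_unequal_means(self):
        t, _, p = unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and t < 0 and p == 0


class TestSummaryT:
    def test_equal_means_zero(self):
        t, _, _ = t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0

    def test_doubling_ses_halves_t(self):
        t1, _, _ = t_from_summary(10.0, 1.0, 10, 8.0, 1.0, 10)
        t2, _, _ = t_from_summary(10.0, 2.0, 10, 8.0, 2.0, 10)
        assert t2 == pytest.approx(t1 / 2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 0.0, 5, 2.0, 1.0, 5)


def test_critical_t_df30():
    assert critical_t(0.05, 30) == pytest.approx(2.042, abs=5e-4)


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_corr(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman_corr(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_known_rank_value(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        rho, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)


class TestClusterMean:
    def test_singleton_and_uniform(self):
        topo = np.array([[1.0, 3.0], [5.0, 7.0]])
        labels = ["a", "b"]
        np.testing.assert_allclose(cluster_mean(topo, labels, ["b"]), [3.0, 7.0])
        np.testing.assert_allclose(cluster_mean(topo, labels, ["a", "b"]),
                                   [2.0, 6.0])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_mean(np.ones((2, 2)), ["a", "b"], [])


def chain_adjacency(n):
    return AdjacencyGraph(labels=[f"c{i}" for i in range(n)],
                          edges={(i, i + 1) for i in range(n - 1)})


class TestSnPM:
    def test_duplicated_groups_no_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (8, 16))
        res = snpm_cluster_test(a, a.copy(), chain_adjacency(16), n_perm=256,
                                seed=0)
        assert res == []

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (8, 16))
        b = rng.normal(0.9, 1, (8, 16))
        r1 = snpm_cluster_test(a, b, chain_adjacency(16), n_perm=512, seed=42)
        r2 = snpm_cluster_test(a, b, chain_adjacency(16), n_perm=512, seed=42)
        assert [(c.channels, c.stat, c.p) for c in r1] == \
               [(c.channels, c.stat, c.p) for c in r2]

    def test_localized_shift_recovered(self):
        # +3 SD on 10 adjacent channels of 64: the cluster should cover most
        # of them and reach significance in the large majority of replicates
        mon = make_montage(64)
        adj = build_adjacency(mon)
        nbrs = adj.neighbors()
        region, queue = [0], [0]   # grow a connected 10-channel patch by BFS
        while queue and len(region) < 10:
            for nb in nbrs[queue.pop(0)]:
                if nb not in region and len(region) < 10:
                    region.append(nb)
                    queue.append(nb)
        hits = 0
        rng = np.random.default_rng(3)
        n_rep = 10
        for _ in range(n_rep):
            a = rng.normal(0, 1, (16, 64))
            b = rng.normal(0, 1, (16, 64))
            a[:, region] += 3.0
            res = snpm_cluster_test(a, b, adj, n_perm=512, seed=rng)
            sig = [c for c in res if c.p < 0.05 and c.sign > 0]
            if sig and len(set(sig[0].channels)
                           & {adj.labels[i] for i in region}) >= 8:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_exact_enumeration_small_design(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (3, 5)) + 4.0
        b = rng.normal(0, 1, (3, 5))
        res = snpm_cluster_test(a, b, chain_adjacency(5), exact=True, seed=0)
        assert res
        # C(6,3) = 20 relabelings; the observed one is the most extreme
        assert min(c.p for c in res) >= 1 / 20

    def test_batch_components_match_networkx(self):
        nx = pytest.importorskip("networkx")
        from somnotype.stats_topo import _max_cluster_stat_batch

        rng = np.random.default_rng(5)
        mon = make_montage(32)
        adj = build_adjacency(mon)
        mat = adj.matrix()
        tmaps = rng.normal(0, 1.6, (50, 32))
        ours = _max_cluster_stat_batch(tmaps, mat, 2.042, "mass")
        g = nx.from_numpy_array(mat)
        for k in range(50):
            best = 0.0
            for sign in (1, -1):
                supra = set(np.nonzero(sign * tmaps[k] > 2.042)[0])
                sub = g.subgraph(supra)
                for comp in nx.connected_components(sub):
                    best = max(best, float(np.abs(tmaps[k][list(comp)]).sum()))
            assert ours[k] == pytest.approx(best)

    def test_permutation_null_is_calibrated(self):
        # small-scale check of FWER validity; the full-size calibration runs
        # in the acceptance suite
        rng = np.random.default_rng(6)
        adj = chain_adjacency(16)
        rej = 0
        n_data = 200
        for _ in range(n_data):
            a = rng.normal(0, 1, (8, 16))
            b = rng.normal(0, 1, (8, 16))
            res = snpm_cluster_test(a, b, adj, n_perm=256, seed=rng)
            if res and min(c.p for c in res) < 0.05:
                rej += 1
        assert rej / n_data == pytest.approx(0.05, abs=0.035)
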