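"""Cluster permutation test: oracles, bookkeeping and antisymmetry."""

import numpy as np
import pytest
from scipy import stats

from mibci.clusterstat import (
    Cluster,
    ClusterConfig,
    channel_adjacency,
    cluster_pvalues,
    paired_t_map,
    permutation_null,
    run_cluster_test,
    threshold_clusters,
    _connected_clusters,
)


def flood_fill_oracle(mask, chan_adj):
    """Exhaustive stack-based flood fill over the channel/freq/time grid."""
    seen = np.zeros_like(mask, bool)
    comps = []
    n_ch, n_f, n_t = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            c, f, t = stack.pop()
            comp.append((c, f, t))
            neighbors = [(c, f, t - 1), (c, f, t + 1),
                         (c, f - 1, t), (c, f + 1, t)]
            neighbors += [(c2, f, t) for c2 in np.nonzero(chan_adj[c])[0]]
            for nb in neighbors:
                c2, f2, t2 = nb
                if 0 <= c2 < n_ch and 0 <= f2 < n_f and 0 <= t2 < n_t:
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.fixture(scope="module")
def adj():
    return channel_adjacency()


class TestPairedT:
    def test_identical_maps_zero_t(self):
        a = np.random.default_rng(0).normal(size=(8, 4, 3, 5))
        assert not paired_t_map(a - a).any()

    def test_zero_variance_bins_flagged_as_zero(self):
        diffs = np.ones((6, 2, 2, 2))  # constant difference, sd = 0
        t = paired_t_map(diffs)
        assert not t.any()

    def test_matches_per_bin_scalar_oracle(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0.2, 1.0, size=(12, 3, 4, 5))
        t = paired_t_map(diffs)
        for idx in np.ndindex(3, 4, 5):
            d = diffs[(slice(None),) + idx]
            expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert t[idx] == pytest.approx(expected, rel=1e-12)
            # cross-check against the library paired t-test
            t_sp, _ = stats.ttest_1samp(d, 0.0)
            assert t[idx] == pytest.approx(t_sp, rel=1e-9)


class TestConnectedComponents:
    def test_singleton_and_block(self, adj):
        t_map = np.zeros((16, 6, 7))
        t_map[0, 2, 3] = 10.0           # isolated bin
        t_map[5, 1:4, 1:4] = 10.0       # 3x3 block on one channel
        clusters = threshold_clusters(t_map, df=17, chan_adj=adj)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 9]

    def test_subthreshold_map_no_clusters(self, adj):
        assert threshold_clusters(np.zeros((16, 4, 4)), 17, adj) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_flood_fill_on_random_masks(self, seed, adj):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 5, 8)) < 0.3
        ours = {frozenset(map(tuple, c)) for c in _connected_clusters(mask, adj)}
        assert ours == flood_fill_oracle(mask, adj)

    def test_channel_dimension_connects_through_adjacency(self, adj):
        # C3 (idx 3) and C1 (idx 4) are neighbors; C3 and P4 are not
        mask = np.zeros((16, 1, 1), bool)
        mask[3] = mask[4] = mask[15] = True
        comps = _connected_clusters(mask, adj)
        assert sorted(len(c) for c in comps) == [1, 2]


class TestPermutationNull:
    def test_null_size_bookkeeping(self, adj):
        rng = np.random.default_rng(0)
        diffs = rng.normal(size=(18, 16, 2, 3))
        null = permutation_null(diffs, adj, ClusterConfig(n_permutations=150,
                                                          seed=1))
        assert null.shape == (150,)
        assert (null >= 0).all()

    def test_all_zero_maps_zero_null(self, adj):
        null = permutation_null(np.zeros((6, 16, 2, 2)), adj,
                                ClusterConfig(n_permutations=120, seed=0))
        assert not null.any()

    def test_exhaustive_at_n6_matches_full_enumeration(self, adj):
        """2^6 sign-flip enumeration equals the exhaustive oracle."""
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.5, 1.0, size=(6, 16, 1, 2))
        null = permutation_null(diffs, adj, ClusterConfig(exhaustive=True))
        assert null.shape == (64,)
        # independent oracle: loop over all sign patterns explicitly
        from itertools import product
        t_crit = stats.t.ppf(0.975, 5)
        expected = []
        for signs in product([-1.0, 1.0], repeat=6):
            d = diffs * np.asarray(signs)[:, None, None, None]
            t = paired_t_map(d)
            best = 0.0
            for sgn, m in ((1, t > t_crit), (-1, t < -t_crit)):
                for comp in _connected_clusters(m, adj):
                    best = max(best, abs(t[tuple(comp.T)].sum()))
            expected.append(best)
        assert np.allclose(np.sort(null), np.sort(expected))

    def test_monte_carlo_close_to_exact_at_small_n(self, adj):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.8, 1.0, size=(8, 16, 1, 2))
        exact = permutation_null(diffs, adj, ClusterConfig(exhaustive=True))
        mc = permutation_null(diffs, adj, ClusterConfig(n_permutations=2000,
                                                        seed=9))
        t_map = paired_t_map(diffs)
        clusters = threshold_clusters(t_map, 7, adj)
        if clusters:
            mass = abs(clusters[0].mass)
            p_exact = (1 + np.sum(exact >= mass)) / (1 + exact.size)
            p_mc = (1 + np.sum(mc >= mass)) / (1 + mc.size)
            tol = 2 * np.sqrt(p_exact * (1 - p_exact) / 2000) + 1e-3
            assert abs(p_mc - p_exact) <= tol

    def test_determinism(self, adj):
        diffs = np.random.default_rng(5).normal(size=(10, 16, 2, 2))
        cfg = ClusterConfig(n_permutations=200, seed=42)
        a = permutation_null(diffs, adj, cfg)
        b = permutation_null(diffs, adj, cfg)
        assert np.array_equal(a, b)


class TestPValues:
    def test_exceedance_formula(self):
        null = np.arange(5000, dtype=float)
        c = Cluster(bins=np.array([[0, 0, 0]]), mass=1e9, sign=1)
        cluster_pvalues([c], null)
        assert c.p_value == pytest.approx(1 / 5001)

    def test_zero_mass_p_one(self):
        null = np.abs(np.random.default_rng(0).normal(size=100))
        c = Cluster(bins=np.array([[0, 0, 0]]), mass=0.0, sign=1)
        cluster_pvalues([c], null)
        assert c.p_value == 1.0

    def test_monotone_in_mass(self):
        null = np.linspace(0, 10, 500)
        masses = [1.0, 3.0, 7.0, 11.0]
        clusters = [Cluster(np.array([[0, 0, 0]]), m, 1) for m in masses]
        cluster_pvalues(clusters, null)
        ps = [c.p_value for c in clusters]
        assert ps == sorted(ps, reverse=True)


class TestRunClusterTest:
    def test_label_swap_antisymmetry(self, adj):
        rng = np.random.default_rng(6)
        a = rng.normal(-0.3, 0.1, size=(12, 16, 3, 4))
        b = rng.normal(0.0, 0.1, size=(12, 16, 3, 4))
        cfg = ClusterConfig(n_permutations=300, seed=3)
        r1 = run_cluster_test(a, b, adj, cfg)
        r2 = run_cluster_test(b, a, adj, cfg)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(-c.mass for c in r2.clusters)
        assert np.allclose(m1, m2)
        p1 = sorted(c.p_value for c in r1.clusters)
        p2 = sorted(c.p_value for c in r2.clusters)
        assert np.allclose(p1, p2)

    def test_planted_effect_found(self, adj):
        rng = np.random.default_rng(7)
        n = 18
        a = rng.normal(0.0, 0.1, size=(n, 16, 4, 6))
        b = rng.normal(0.0, 0.1, size=(n, 16, 4, 6))
        a[:, [3, 12], :2, 2:] -= 0.2  # bilateral alpha-like effect at C3/C4
        res = run_cluster_test(a, b, adj, ClusterConfig(n_permutations=500,
                                                        seed=1))
        assert len(res.significant) >= 1
        top = res.significant[0]
        assert top.sign == -1
        assert {3, 12} & set(top.bins[:, 0])

    def test_channel_only_topography_input(self, adj):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(10, 16))
        b = rng.normal(size=(10, 16))
        res = run_cluster_test(a, b, adj, ClusterConfig(n_permutations=200,
                                                        seed=0))
        assert res.t_map.shape == (16, 1, 1)

    def test_mismatched_shapes_rejected(self, adj):
        with pytest.raises(ValueError):
            run_cluster_test(np.zeros((5, 16, 2, 2)), np.zeros((5, 16, 2, 3)),
                             adj)
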