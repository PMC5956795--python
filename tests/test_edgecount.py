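"""k-MST construction and the edge-count tests: hand-computed fixtures,
an independent Cramer-rule oracle, permutation-moment checks, and the
label-symmetry / edge-partition invariants."""

import numpy as np
import pytest

from dcenet.edgecount import (
    KMSTError,
    SimilarityGraph,
    build_kmst,
    count_edges,
    edge_count_moments,
    multi_group_test,
    permutation_test,
    two_group_test,
)
from oracles import cramer_two_group_S


class TestBuildKmst:
    def test_collinear_points_mst(self):
        g = build_kmst(np.array([0.0, 1.0, 2.0, 3.0]), k=1)
        assert g.edges.tolist() == [[0, 1], [1, 2], [2, 3]]

    def test_mst_has_n_minus_1_edges_and_is_connected(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(25, 2))
        g = build_kmst(pts, k=1)
        assert g.n_edges == 24
        import networkx as nx

        nxg = nx.Graph(map(tuple, g.edges))
        assert nx.is_connected(nxg)

    def test_mst_weight_matches_networkx(self):
        # independent oracle: total MST weight from networkx's Kruskal
        import networkx as nx
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        d = squareform(pdist(pts))
        g = build_kmst(pts, k=1)
        mine = sum(d[i, j] for i, j in g.edges)
        nxg = nx.Graph()
        for i in range(20):
            for j in range(i + 1, 20):
                nxg.add_edge(i, j, weight=d[i, j])
        ref = sum(
            attrs["weight"]
            for _, _, attrs in nx.minimum_spanning_edges(nxg, algorithm="kruskal")
        )
        assert mine == pytest.approx(ref, rel=1e-12)

    def test_three_mst_on_six_points_exhausts_complete_graph(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        g = build_kmst(pts, k=3)
        assert g.n_edges == 15  # 3 * (6 - 1) = C(6, 2): all of K_6

    def test_trees_are_edge_disjoint(self):
        rng = np.random.default_rng(3)
        g = build_kmst(rng.normal(size=(12, 2)), k=3)
        seen = {tuple(e) for e in g.edges}
        assert len(seen) == g.n_edges == 33

    def test_infeasible_round_raises_with_round_number(self):
        # K_6 cannot hold 4 edge-disjoint spanning trees (15 < 4*5); the
        # greedy construction may already disconnect at round 3
        rng = np.random.default_rng(4)
        with pytest.raises(KMSTError, match="round [34]"):
            build_kmst(rng.normal(size=(6, 2)), k=4)


class TestCountEdges:
    def test_single_group_takes_all_edges(self):
        g = build_kmst(np.arange(5.0), k=1)
        r0, r = count_edges(g, np.zeros(5, int))
        assert r0 == 0 and r.tolist() == [4]

    def test_two_separated_clusters(self):
        g = build_kmst(np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0]), k=1)
        r0, r = count_edges(g, np.array([0, 0, 0, 1, 1, 1]))
        assert r.tolist() == [2, 2] and r0 == 1

    def test_edge_partition_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = build_kmst(rng.normal(size=(15, 2)), k=2)
            labels = rng.integers(0, 3, size=15)
            while np.bincount(labels, minlength=3).min() == 0:
                labels = rng.integers(0, 3, size=15)
            r0, r = count_edges(g, labels)
            assert r0 + r.sum() == g.n_edges

    def test_label_length_mismatch(self):
        g = build_kmst(np.arange(5.0), k=1)
        with pytest.raises(ValueError):
            count_edges(g, np.zeros(4, int))


class TestMoments:
    def test_mu_on_balanced_mst_fixture(self):
        rng = np.random.default_rng(6)
        g = build_kmst(rng.normal(size=(6, 2)), k=1)
        mu, _, _ = edge_count_moments(g, (3, 3))
        assert mu.tolist() == [1.0, 1.0]  # 5 * 3*2 / (6*5)

    def test_C_on_path_graph(self):
        g = SimilarityGraph(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        _, _, C = edge_count_moments(g, (3, 3))
        assert C == 4.0  # degrees (1,2,2,2,2,1): 18/2 - 5

    @pytest.mark.parametrize("k,sizes", [(1, (6, 6)), (3, (5, 4, 3))])
    def test_moments_match_random_labelings(self, k, sizes):
        rng = np.random.default_rng(7)
        N = sum(sizes)
        g = build_kmst(rng.normal(size=(N, 2)), k=k)
        mu, Sigma, _ = edge_count_moments(g, sizes)
        base = np.repeat(np.arange(len(sizes)), sizes)
        B = 4000
        Rs = np.empty((B, len(sizes)))
        for b in range(B):
            _, Rs[b] = count_edges(g, rng.permutation(base))
        se_mu = Rs.std(axis=0, ddof=1) / np.sqrt(B)
        assert np.all(np.abs(Rs.mean(axis=0) - mu) < 3 * se_mu + 1e-12)
        centered = Rs - Rs.mean(axis=0)
        for i in range(len(sizes)):
            for j in range(len(sizes)):
                prods = centered[:, i] * centered[:, j]
                se = prods.std(ddof=1) / np.sqrt(B)
                assert abs(prods.mean() - Sigma[i, j]) < 3 * se + 1e-12


class TestTwoGroupTest:
    def test_matches_cramer_rule_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = build_kmst(rng.normal(size=(20, 2)), k=2)
            labels = np.array([0] * 12 + [1] * 8)
            rng.shuffle(labels)
            res = two_group_test(g, labels)
            assert res.df == 2
            assert res.S == pytest.approx(cramer_two_group_S(g, labels), abs=1e-9)

    def test_counts_at_expectation_give_zero_statistic(self):
        g = SimilarityGraph(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        mu, Sigma, _ = edge_count_moments(g, (3, 3))
        # feed R = mu through the quadratic form directly
        from dcenet.edgecount import _quadratic

        S, df, _ = _quadratic(mu - mu, Sigma)
        assert S == 0.0

    def test_separated_clusters_are_significant(self):
        x = np.concatenate([np.random.default_rng(9).normal(0, 0.1, 20),
                            np.random.default_rng(10).normal(10, 0.1, 20)])
        g = build_kmst(x, k=1)
        labels = np.array([0] * 20 + [1] * 20)
        assert two_group_test(g, labels).p_value < 1e-6

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(11)
        g = build_kmst(rng.normal(size=(18, 2)), k=3)
        labels = np.array([0] * 10 + [1] * 8)
        a = two_group_test(g, labels)
        b = two_group_test(g, 1 - labels)
        assert a.S == pytest.approx(b.S, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.R.tolist() == b.R[::-1].tolist()


class TestMultiGroupTest:
    def test_two_groups_identical_to_two_group_test(self):
        rng = np.random.default_rng(12)
        g = build_kmst(rng.normal(size=(16, 2)), k=2)
        labels = np.array([0] * 9 + [1] * 7)
        a = two_group_test(g, labels)
        b = multi_group_test(g, labels)
        assert a.S == b.S and a.p_value == b.p_value  # bit-for-bit

    def test_df_equals_group_count(self):
        rng = np.random.default_rng(13)
        g = build_kmst(rng.normal(size=(20, 2)), k=3)
        labels = np.repeat([0, 1, 2, 3], 5)
        assert multi_group_test(g, labels).df == 4

    def test_mean_statistic_near_chi2_mean_under_permutation(self):
        rng = np.random.default_rng(14)
        g = build_kmst(rng.normal(size=(60, 2)), k=3)
        base = np.repeat([0, 1, 2], 20)
        mu, Sigma, _ = edge_count_moments(g, (20, 20, 20))
        Minv = np.linalg.inv(Sigma)
        B = 5000
        Ss = np.empty(B)
        for b in range(B):
            _, R = count_edges(g, rng.permutation(base))
            d = R - mu
            Ss[b] = d @ Minv @ d
        se = Ss.std(ddof=1) / np.sqrt(B)
        assert abs(Ss.mean() - 3.0) < 3 * se


class TestPermutationTest:
    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(15)
        g = build_kmst(rng.normal(size=(20, 2)), k=2)
        labels = np.array([0] * 10 + [1] * 10)
        assert permutation_test(g, labels, 200, seed=1) == permutation_test(g, labels, 200, seed=1)

    def test_separated_clusters_reach_floor_region(self):
        pts = np.concatenate([np.zeros(10) + np.arange(10) * 0.01,
                              10 + np.arange(10) * 0.01])
        g = build_kmst(pts, k=1)
        labels = np.array([0] * 10 + [1] * 10)
        p = permutation_test(g, labels, n_perm=499, seed=2)
        assert p < 0.01

    def test_chi2_close_to_permutation_p(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(100, 2))
        g = build_kmst(pts, k=3)
        labels = np.array([0] * 50 + [1] * 50)
        rng.shuffle(labels)
        chi2_p = two_group_test(g, labels).p_value
        perm_p = permutation_test(g, labels, n_perm=2000, seed=3)
        assert abs(chi2_p - perm_p) < 0.05
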