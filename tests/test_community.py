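"""Community detection, strength (per-community modularity) and corruption."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from csgae import (
    CommunityPartition,
    SpatialDataset,
    SpotGraph,
    TissueSimSpec,
    attribute_penalty,
    community_strength,
    corrupt_edges,
    corrupt_features,
    detect_communities,
    edge_penalty,
    generate_views,
    preprocess,
    simulate_tissue,
)

from conftest import toy_dataset


def random_graph_and_partition(seed, n=30, p=0.2, kmax=5):
    rng = np.random.default_rng(seed)
    A = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    A = A + A.T
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    k = rng.integers(2, kmax + 1)
    assign = rng.integers(0, k, size=n)
    assign[:k] = np.arange(k)  # every community inhabited
    return SpotGraph(n, sp.csr_matrix(A), "spatial"), CommunityPartition(assign)


class TestCommunityStrength:
    def test_single_community_is_zero(self):
        g, _ = random_graph_and_partition(0)
        part = CommunityPartition(np.zeros(30, dtype=int))
        s = community_strength(g, part)
        assert s.shape == (1,)
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_bridge_exact(self, two_triangles):
        g, part = two_triangles
        s = community_strength(g, part)
        expected = float(Fraction(3, 7) - Fraction(49, 196))  # = 5/28
        assert s[0] == pytest.approx(expected, abs=1e-15)
        assert s[1] == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(5 / 28)

    @pytest.mark.parametrize("seed", range(50))
    def test_sum_equals_newman_girvan_modularity(self, seed):
        g, part = random_graph_and_partition(seed)
        s = community_strength(g, part)
        G = nx.from_scipy_sparse_array(g.adjacency)
        comms = [set(np.flatnonzero(part.assignment == c))
                 for c in range(part.n_communities)]
        Q = nx.algorithms.community.modularity(G, comms)
        assert s.sum() == pytest.approx(Q, abs=1e-10)

    def test_edgeless_graph_rejected(self):
        g = SpotGraph(4, sp.csr_matrix((4, 4)), "spatial")
        with pytest.raises(ValueError, match="edgeless"):
            community_strength(g, CommunityPartition(np.zeros(4, dtype=int)))

    def test_permutation_equivariance(self):
        g, part = random_graph_and_partition(3)
        s = community_strength(g, part)
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        P = sp.coo_matrix((np.ones(30), (np.arange(30), perm)), shape=(30, 30))
        gp = SpotGraph(30, (P @ g.adjacency @ P.T).tocsr(), "spatial")
        sp_perm = community_strength(gp, CommunityPartition(part.assignment[perm]))
        # community ids may be relabeled by contiguity; compare as multisets
        np.testing.assert_allclose(np.sort(s), np.sort(sp_perm), atol=1e-12)


class TestDetectCommunities:
    def test_two_well_separated_blobs(self):
        spec = TissueSimSpec(grid_shape=(10, 20), n_domains=2, n_genes=60,
                             markers_per_domain=10, marker_fold_change=10.0,
                             dropout_rate=0.0, dispersion=0.05, seed=5)
        ds = preprocess(simulate_tissue(spec), 1e4, 3000)
        part = detect_communities(ds, resolution=1.0, seed=0)
        assert adjusted_rand_score(ds.labels, part.assignment) == pytest.approx(1.0)

    def test_resolution_zero_limit_single_community(self, bands_small_pp):
        part = detect_communities(bands_small_pp, resolution=1e-4, seed=0)
        assert part.n_communities == 1

    def test_deterministic_under_seed(self, bands_small_pp):
        a = detect_communities(bands_small_pp, seed=3)
        b = detect_communities(bands_small_pp, seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_contiguous_ids(self, bands_small_pp):
        part = detect_communities(bands_small_pp, seed=0)
        assert set(np.unique(part.assignment)) == set(range(part.n_communities))

    def test_indicator_rows_sum_to_one(self, bands_small_pp):
        part = detect_communities(bands_small_pp, seed=0)
        np.testing.assert_array_equal(part.indicator.sum(axis=1), 1.0)


class TestAttributePenalty:
    def test_null_strength_gives_zeros(self):
        ds = toy_dataset(n=6, p=5)
        part = CommunityPartition(np.array([0, 0, 0, 1, 1, 1]),
                                  np.zeros(2))
        np.testing.assert_array_equal(attribute_penalty(ds, part), 0.0)

    def test_top_gene_has_zero_penalty(self):
        ds = toy_dataset(n=6, p=5, seed=2)
        part = CommunityPartition(np.array([0, 0, 0, 1, 1, 1]),
                                  np.array([0.3, 0.1]))
        p = attribute_penalty(ds, part)
        votes = np.abs(ds.dense_expression()).T @ part.node_strength()
        assert p[np.argmax(votes)] == pytest.approx(0.0)

    def test_matches_spreadsheet_oracle(self):
        # 6 nodes, 5 genes, hand-assigned strengths
        X = np.arange(30, dtype=float).reshape(6, 5)
        ds = SpatialDataset(
            X, np.column_stack([np.arange(6.0), np.zeros(6)]),
            [f"g{j}" for j in range(5)], [f"s{i}" for i in range(6)],
        )
        strengths = np.array([0.4, -0.2])
        part = CommunityPartition(np.array([0, 1, 0, 1, 0, 1]), strengths)
        s_node = strengths[[0, 1, 0, 1, 0, 1]]
        raw = np.log1p(np.maximum((np.abs(X) * s_node[:, None]).sum(axis=0), 0.0))
        expected = (raw.max() - raw) / (raw.max() - raw.mean())
        np.testing.assert_allclose(attribute_penalty(ds, part), expected, atol=1e-12)


class TestCorruptFeatures:
    def test_zero_lambda_is_identity(self):
        X = np.random.default_rng(0).normal(size=(8, 6))
        mask, Xt = corrupt_features(X, np.random.default_rng(1).random(6), 0.0, 7)
        np.testing.assert_array_equal(Xt, X)
        np.testing.assert_array_equal(mask, 1.0)

    def test_certain_masking(self):
        X = np.ones((4, 3))
        p_a = np.array([1.0, 0.0, 1.0])
        mask, Xt = corrupt_features(X, p_a, 1.0, 3)
        np.testing.assert_array_equal(Xt[:, 0], 0.0)
        np.testing.assert_array_equal(Xt[:, 2], 0.0)
        np.testing.assert_array_equal(Xt[:, 1], 1.0)

    def test_hadamard_structure(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 20))
        _, Xt = corrupt_features(X, rng.random(20), 0.8, 11)
        assert np.all((Xt == X) | (Xt == 0.0))

    def test_bernoulli_calibration(self):
        # empirical masking frequency ~ p*lambda over 10k seeded draws
        p_a = np.array([0.3])
        masked = sum(
            1 - corrupt_features(np.ones((1, 1)), p_a, 1.0, s)[0][0]
            for s in range(10_000)
        )
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(masked / 10_000 - 0.3) < 3 * se

    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            corrupt_features(np.ones((2, 2)), np.zeros(2), 1.5, 0)


class TestEdgePenalty:
    def test_single_community_all_zero(self):
        g, _ = random_graph_and_partition(1)
        part = CommunityPartition(np.zeros(30, dtype=int))
        part = part.with_strength(community_strength(g, part))
        np.testing.assert_array_equal(edge_penalty(g, part), 0.0)

    def test_inter_community_strictly_negative(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        p = edge_penalty(g, part)
        edges = g.edge_list()
        inter = part.assignment[edges[:, 0]] != part.assignment[edges[:, 1]]
        assert np.all(p[inter] < 0)
        assert np.all(p[~inter] >= 0)

    def test_bridge_fixture_hand_evaluation(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        p = edge_penalty(g, part)
        edges = [tuple(e) for e in g.edge_list()]
        bridge = edges.index((2, 3))
        # both communities share strength 5/28: intra penalties all 0 (constant),
        # the bridge is strictly negative
        for idx, e in enumerate(edges):
            if idx == bridge:
                assert p[idx] < 0
            else:
                assert p[idx] == pytest.approx(0.0)


class TestCorruptEdges:
    def test_zero_lambda_is_identity(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        At = corrupt_edges(g, edge_penalty(g, part), 0.0, 5)
        np.testing.assert_array_equal(At.toarray(), g.adjacency.toarray())

    def test_inter_community_edges_always_survive(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        p = edge_penalty(g, part)
        for seed in range(200):
            At = corrupt_edges(g, p, 1.0, seed)
            assert At[2, 3] == 1.0

    def test_subset_of_source_and_symmetric(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        p = np.full(g.n_edges, 0.5)
        At = corrupt_edges(g, p, 1.0, 9)
        D = At.toarray()
        np.testing.assert_array_equal(D, D.T)
        assert np.all(D <= g.adjacency.toarray())

    def test_bernoulli_calibration(self):
        # single-edge graph, keep-probability 0.7
        A = sp.csr_matrix(np.array([[0.0, 1], [1, 0]]))
        g = SpotGraph(2, A, "spatial")
        kept = sum(
            corrupt_edges(g, np.array([0.3]), 1.0, s).nnz // 2
            for s in range(10_000)
        )
        se = np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(kept / 10_000 - 0.7) < 3 * se


class TestGenerateViews:
    def make_inputs(self, two_triangles):
        g, part = two_triangles
        part = part.with_strength(community_strength(g, part))
        X = np.random.default_rng(0).normal(size=(6, 5)) ** 2
        return g, X, part

    def test_all_zero_lambdas_identity(self, two_triangles):
        g, X, part = self.make_inputs(two_triangles)
        lam = {k: 0.0 for k in ("lambda_a1", "lambda_a2", "lambda_e1", "lambda_e2")}
        v1, v2 = generate_views(g, X, part, lam, seed=0)
        for v in (v1, v2):
            np.testing.assert_array_equal(v.features, X)
            np.testing.assert_array_equal(v.adjacency.toarray(), g.adjacency.toarray())

    def test_fixed_seed_bitwise_identical(self, two_triangles):
        g, X, part = self.make_inputs(two_triangles)
        a1, a2 = generate_views(g, X, part, seed=123)
        b1, b2 = generate_views(g, X, part, seed=123)
        np.testing.assert_array_equal(a1.features, b1.features)
        np.testing.assert_array_equal(a2.features, b2.features)
        np.testing.assert_array_equal(a1.adjacency.toarray(), b1.adjacency.toarray())
        np.testing.assert_array_equal(a2.adjacency.toarray(), b2.adjacency.toarray())

    def test_views_use_independent_draws(self, two_triangles):
        g, X, part = self.make_inputs(two_triangles)
        lam = dict(lambda_a1=0.9, lambda_a2=0.9, lambda_e1=0.9, lambda_e2=0.9)
        differ = False
        for seed in range(20):
            v1, v2 = generate_views(g, X, part, lam, seed=seed)
            if not np.array_equal(v1.gene_mask, v2.gene_mask):
                differ = True
                break
        assert differ

    def test_monotone_expected_corruption(self, two_triangles):
        g, X, part = self.make_inputs(two_triangles)
        p_a = attribute_penalty(
            SpatialDataset(
                X, np.zeros((6, 2)), [f"g{j}" for j in range(5)],
                [f"s{i}" for i in range(6)],
            ),
            part,
        )
        masked = []
        for lam in (0.2, 0.9):
            total = sum(
                5 - corrupt_features(X, p_a, lam, s)[0].sum() for s in range(400)
            )
            masked.append(total)
        assert masked[0] <= masked[1]


def test_strength_in_modularity_bounds():
    for seed in range(10):
        g, part = random_graph_and_partition(seed)
        s = community_strength(g, part)
        assert -1.0 <= s.sum() <= 1.0
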