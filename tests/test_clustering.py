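"""Leiden clustering, graph-abstraction connectivity, UMAP, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score, silhouette_score

from neuroshape import (
    build_knn_graph,
    cluster_spatial_profile,
    leiden_cluster,
    paga_connectivity,
    representative_cell,
    umap_embed,
)


def _blobs(n_per=100, sep=10.0, dim=8, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, dim))
    centers[1, 0] = sep
    centers[2, 1] = sep
    x = np.vstack([rng.normal(c, 1.0, size=(n_per, dim)) for c in centers])
    y = np.repeat([0, 1, 2], n_per)
    return x, y


def _paga_oracle(labels, adj):
    """Independent edge-enumeration implementation."""
    labels = np.asarray(labels)
    ids = list(np.unique(labels))
    n = len(labels)
    coo = sparse.triu(adj, k=1).tocoo()
    edges = list(zip(coo.row, coo.col))
    e_total = len(edges)
    k = len(ids)
    out = np.zeros((k, k))
    for i, ci in enumerate(ids):
        for j, cj in enumerate(ids):
            if i == j:
                continue
            obs = sum(
                1 for a, b in edges
                if {labels[a], labels[b]} == {ci, cj}
            )
            ni = (labels == ci).sum()
            nj = (labels == cj).sum()
            expected = e_total * ni * nj / (n * (n - 1) / 2.0)
            out[i, j] = obs / expected
    return out


class TestLeiden:
    def test_planted_blobs_perfect_ari(self):
        x, y = _blobs()
        labels, _ = leiden_cluster(x, k_neighbors=30, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_identical_points_single_cluster(self):
        x = np.zeros((50, 4))
        labels, _ = leiden_cluster(x, k_neighbors=10, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_given_seed(self):
        x, _ = _blobs(seed=4)
        l1, _ = leiden_cluster(x, 20, seed=3)
        l2, _ = leiden_cluster(x, 20, seed=3)
        assert np.array_equal(l1, l2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            leiden_cluster(np.zeros((5, 2)), k_neighbors=10)

    def test_relabeling_by_median_distance(self):
        """Cluster ids must ascend with the members' median d."""
        x, y = _blobs(n_per=60, seed=2)
        rng = np.random.default_rng(0)
        d = np.empty(len(y))
        d[y == 0] = rng.uniform(0.6, 0.8, (y == 0).sum())
        d[y == 1] = rng.uniform(0.0, 0.2, (y == 1).sum())
        d[y == 2] = rng.uniform(0.3, 0.5, (y == 2).sum())
        labels, _ = leiden_cluster(x, 20, seed=0, order_by=d)
        medians = [np.median(d[labels == c]) for c in sorted(np.unique(labels))]
        assert medians == sorted(medians)


class TestPagaConnectivity:
    def test_disconnected_clusters_zero(self):
        adj = sparse.lil_matrix((6, 6))
        for a, b in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            adj[a, b] = adj[b, a] = 1.0
        conn = paga_connectivity(np.array([0, 0, 0, 1, 1, 1]), adj.tocsr())
        assert conn[0, 1] == 0.0

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            n = 40
            labels = rng.integers(0, 3, n)
            dense = rng.random((n, n)) < 0.15
            dense = np.triu(dense, 1)
            adj = sparse.csr_matrix(dense + dense.T)
            conn = paga_connectivity(labels, adj)
            oracle = _paga_oracle(labels, adj)
            assert np.allclose(conn, oracle, atol=0.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            n = 30
            labels = rng.integers(0, 4, n)
            dense = np.triu(rng.random((n, n)) < 0.2, 1)
            adj = sparse.csr_matrix(dense + dense.T)
            if len(np.unique(labels)) < 2:
                continue
            conn = paga_connectivity(labels, adj)
            assert np.allclose(conn, conn.T)
            assert np.all(np.diag(conn) == 0.0)

    def test_complete_graph_split(self):
        n = 12
        dense = np.ones((n, n), dtype=bool)
        np.fill_diagonal(dense, False)
        adj = sparse.csr_matrix(np.triu(dense, 1) + np.triu(dense, 1).T)
        labels = np.array([0] * 6 + [1] * 6)
        conn = paga_connectivity(labels, adj)
        assert conn[0, 1] == pytest.approx(_paga_oracle(labels, adj)[0, 1])


class TestUmap:
    def test_deterministic_given_seed(self):
        x, y = _blobs(n_per=40)
        labels, adj = leiden_cluster(x, 15, seed=0)
        conn = paga_connectivity(labels, adj)
        e1 = umap_embed(x, labels, conn, adj, seed=0)
        e2 = umap_embed(x, labels, conn, adj, seed=0)
        assert np.array_equal(e1, e2)

    def test_blobs_separate_in_embedding(self):
        x, y = _blobs(n_per=60)
        labels, adj = leiden_cluster(x, 20, seed=0)
        conn = paga_connectivity(labels, adj)
        xy = umap_embed(x, labels, conn, adj, seed=0)
        assert silhouette_score(xy, labels) > 0.5

    def test_single_cluster_does_not_fail(self):
        x = np.random.default_rng(0).normal(size=(40, 4))
        labels = np.zeros(40, dtype=int)
        xy = umap_embed(x, labels, None, None, seed=0)
        assert xy.shape == (40, 2)


class TestRepresentative:
    def test_singleton_cluster(self):
        scores = np.array([[0.0, 0.0], [5.0, 5.0]])
        rep = representative_cell(np.array([0, 1]), scores)
        assert rep == {0: 0, 1: 1}

    def test_tie_broken_by_lower_id(self):
        scores = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0]])
        rep = representative_cell(np.array([0, 0, 0]), scores)
        # cells 0 and 1 are equidistant from the centroid (0, 2/3)
        d0 = np.linalg.norm(scores[0] - scores.mean(axis=0))
        d1 = np.linalg.norm(scores[1] - scores.mean(axis=0))
        assert d0 == pytest.approx(d1)
        assert rep[0] == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(50, 4))
        labels = rng.integers(0, 4, 50)
        rep = representative_cell(labels, scores)
        for c in np.unique(labels):
            rows = np.nonzero(labels == c)[0]
            cent = scores[rows].mean(axis=0)
            brute = rows[int(np.argmin(np.linalg.norm(scores[rows] - cent,
                                                      axis=1)))]
            assert rep[int(c)] == brute


class TestSpatialProfile:
    def test_constant_distance_quartiles(self):
        loc = pd.DataFrame({"d": [0.5] * 6, "a": [0.0] * 6})
        out = cluster_spatial_profile(np.zeros(6, dtype=int), loc)
        q = out["quartiles"].iloc[0]
        assert q["d_q25"] == q["d_median"] == q["d_q75"] == 0.5

    def test_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1, 40)
        a = rng.uniform(-180, 180, 40)
        loc = pd.DataFrame({"d": d, "a": a})
        out = cluster_spatial_profile(np.zeros(40, dtype=int), loc)["quartiles"]
        assert out["d_median"].item() == pytest.approx(np.percentile(d, 50))
        assert out["a_q25"].item() == pytest.approx(np.percentile(a, 25))

    def test_dv_cluster_straddles_poles(self):
        """A dorsoventral group's angle quartiles bracket +-90 deg."""
        rng = np.random.default_rng(1)
        a_dv = np.concatenate([rng.normal(90, 10, 20), rng.normal(-90, 10, 20)])
        loc = pd.DataFrame({"d": rng.uniform(0, 1, 40), "a": a_dv})
        out = cluster_spatial_profile(np.zeros(40, dtype=int), loc)["quartiles"]
        assert out["a_q25"].item() < -45 and out["a_q75"].item() > 45

    def test_organ_composition_fractions(self):
        loc = pd.DataFrame({
            "d": np.zeros(8), "a": np.zeros(8),
            "organ_id": [0, 0, 0, 0, 1, 1, 1, 1],
        })
        labels = np.array([0, 0, 1, 1, 0, 1, 1, 1])
        comp = cluster_spatial_profile(labels, loc)["organ_composition"]
        assert comp.loc[0, 0] == pytest.approx(0.5)
        assert comp.loc[1, 1] == pytest.approx(0.75)
        assert np.allclose(comp.sum(axis=1), 1.0)
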