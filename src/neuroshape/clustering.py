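"""Unsupervised clustering of cells in shape-mode space.

Cells are embedded in a k-nearest-neighbor graph (Euclidean metric in
mode space, optionally Jaccard-weighted by shared neighborhoods in the
Phenograph style) and partitioned by the Leiden algorithm.  Cluster
relationships are scored by a graph-abstraction connectivity — the
ratio of observed inter-cluster edges to their expectation under
random edge placement — and the population is embedded in 2D by UMAP
initialized from the cluster-graph layout, so the global arrangement
of clusters is stable across seeds.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "build_knn_graph",
    "leiden_cluster",
    "paga_connectivity",
    "umap_embed",
    "representative_cell",
    "cluster_spatial_profile",
]

CONNECTIVITY_DISPLAY_THRESHOLD = 0.1  # applied at plotting only


def build_knn_graph(
    x: np.ndarray, k_neighbors: int = 30, weighting: str = "jaccard"
) -> sparse.csr_matrix:
    """Symmetric kNN adjacency over rows of ``x``.

    With ``weighting="jaccard"`` each edge carries the Jaccard overlap
    of the two endpoints' neighbor sets (Phenograph-style); with
    ``"uniform"`` edges weigh 1.  The union of directed kNN edges is
    symmetrized.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    member = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    adj = member.maximum(member.T)
    if weighting == "uniform":
        return adj.tocsr()
    if weighting != "jaccard":
        raise ValueError("weighting must be 'jaccard' or 'uniform'")
    inter = (member @ member.T).toarray()
    union = 2.0 * k_neighbors - inter
    jac = inter / np.maximum(union, 1.0)
    out = adj.toarray() * np.maximum(jac, 1e-12)  # keep edges with zero overlap
    return sparse.csr_matrix(out)


def _igraph_from_adjacency(adj: sparse.csr_matrix) -> igraph.Graph:
    coo = sparse.triu(adj, k=1).tocoo()
    g = igraph.Graph(
        n=adj.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    return g


def leiden_cluster(
    scores: np.ndarray,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
    weighting: str = "jaccard",
    order_by: np.ndarray | None = None,
    knn_graph: sparse.csr_matrix | None = None,
) -> tuple[np.ndarray, sparse.csr_matrix]:
    """Leiden partition of the shape-mode kNN graph.

    Returns ``(labels, adjacency)``.  Cluster ids are relabeled in
    ascending order of the median of ``order_by`` over members
    (typically the normalized radial distance d, so central clusters
    get low ids); without ``order_by``, by decreasing cluster size.
    Ties break by cluster size then original id.  Deterministic for a
    fixed (data, k, resolution, seed).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    adj = knn_graph if knn_graph is not None else build_knn_graph(
        scores, k_neighbors, weighting
    )
    g = _igraph_from_adjacency(adj)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    ids = np.unique(raw)
    if order_by is not None:
        order_by = np.asarray(order_by, dtype=float)
        keys = [
            (float(np.median(order_by[raw == i])), -int(np.sum(raw == i)), int(i))
            for i in ids
        ]
    else:
        keys = [(-int(np.sum(raw == i)), 0, int(i)) for i in ids]
    order = sorted(range(len(ids)), key=lambda j: keys[j])
    new_of = {int(ids[j]): rank for rank, j in enumerate(order)}
    labels = np.array([new_of[int(r)] for r in raw])
    return labels, adj


def paga_connectivity(
    labels: np.ndarray, knn_graph: sparse.csr_matrix
) -> np.ndarray:
    """Inter-cluster connectivity as observed / expected edge counts.

    For clusters i, j with sizes n_i, n_j, the expectation places the
    graph's E edges uniformly over all vertex pairs, so
    ``expected_ij = E * n_i * n_j / C(N, 2)`` and the connectivity is
    the ratio of the observed inter-cluster edge count to it.  The
    matrix is symmetric with zero diagonal.  Edge weights are ignored:
    connectivity counts edges.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    k = len(ids)
    if k < 2:
        raise ValueError("need at least two clusters")
    pos = {c: i for i, c in enumerate(ids)}
    n = len(labels)
    sizes = np.array([np.sum(labels == c) for c in ids])
    if np.any(sizes == 1):
        warnings.warn("singleton cluster: connectivity estimate is low-confidence")
    coo = sparse.triu(knn_graph, k=1).tocoo()
    e_total = coo.nnz
    obs = np.zeros((k, k))
    for a, b in zip(coo.row, coo.col):
        ca, cb = pos[labels[a]], pos[labels[b]]
        if ca != cb:
            obs[ca, cb] += 1
            obs[cb, ca] += 1
    pairs_total = n * (n - 1) / 2.0
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            expected = e_total * sizes[i] * sizes[j] / pairs_total
            out[i, j] = obs[i, j] / expected if expected > 0 else 0.0
    return out


def _paga_layout(labels: np.ndarray, connectivity: np.ndarray,
                 seed: int) -> np.ndarray:
    """2D positions of cluster centres from the abstracted graph."""
    k = connectivity.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if connectivity[i, j] > 0:
                g.add_edge(i, j, weight=float(connectivity[i, j]))
    pos = nx.spring_layout(g, seed=seed)
    return np.array([pos[i] for i in range(k)])


def umap_embed(
    scores: np.ndarray,
    labels: np.ndarray,
    connectivity: np.ndarray | None = None,
    knn_graph: sparse.csr_matrix | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.5,
) -> np.ndarray:
    """2D UMAP of the mode scores, initialized from the cluster layout.

    Each cell starts at its cluster's position in the abstracted-graph
    layout (plus a small deterministic jitter), which anchors the
    global arrangement; deterministic for a fixed seed.
    """
    import umap  # deferred: numba compilation is slow at import

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    n = len(scores)
    ids = np.unique(labels)
    if connectivity is None or len(ids) < 2:
        init: np.ndarray | str = "spectral" if n > 2 else "random"
        if len(ids) == 1:
            rng = np.random.default_rng(seed)
            init = rng.normal(0, 1e-3, (n, 2))
    else:
        centers = _paga_layout(labels, connectivity, seed)
        pos = {c: centers[i] for i, c in enumerate(ids)}
        rng = np.random.default_rng(seed)
        init = np.array([pos[l] for l in labels]) + rng.normal(0, 0.01, (n, 2))
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        init=init,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(scores), dtype=float)


def representative_cell(
    labels: np.ndarray, scores: np.ndarray, ids: np.ndarray | None = None
) -> dict[int, int]:
    """Per cluster, the member closest to the cluster centroid.

    Distances are Euclidean in (unstandardized) mode-score space; ties
    break by lowest cell id.  Returns ``{cluster: cell id}`` where ids
    default to row numbers.
    """
    labels = np.asarray(labels)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if ids is None:
        ids = np.arange(len(labels))
    ids = np.asarray(ids)
    out: dict[int, int] = {}
    for c in np.unique(labels):
        rows = np.nonzero(labels == c)[0]
        centroid = scores[rows].mean(axis=0)
        dist = np.linalg.norm(scores[rows] - centroid, axis=1)
        best = np.lexsort((ids[rows], dist))[0]
        out[int(c)] = int(ids[rows[best]])
    return out


def cluster_spatial_profile(
    labels: np.ndarray, locations: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Spatial summaries of each cluster.

    ``locations`` needs columns ``d`` and ``a`` (normalized radial
    distance, adjusted angle) and optionally ``organ_id``.  Returns
    per-cluster quartiles of d and a, and — when organ ids are present —
    the per-organ cluster composition (fraction of the organ's cells in
    each cluster).
    """
    labels = np.asarray(labels)
    if len(labels) != len(locations):
        raise ValueError("labels and locations must have matching rows")
    rows = []
    for c in np.unique(labels):
        sel = locations.loc[np.asarray(labels == c)]
        q_d = np.percentile(sel["d"], [25, 50, 75])
        q_a = np.percentile(sel["a"], [25, 50, 75])
        rows.append({
            "cluster": int(c), "n": len(sel),
            "d_q25": q_d[0], "d_median": q_d[1], "d_q75": q_d[2],
            "a_q25": q_a[0], "a_median": q_a[1], "a_q75": q_a[2],
        })
    out = {"quartiles": pd.DataFrame(rows)}
    if "organ_id" in locations.columns:
        comp = (
            pd.DataFrame({"organ_id": locations["organ_id"].to_numpy(),
                          "cluster": labels})
            .groupby(["organ_id", "cluster"]).size().unstack(fill_value=0)
        )
        out["organ_composition"] = comp.div(comp.sum(axis=1), axis=0)
    return out
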