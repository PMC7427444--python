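"""Per-node covariates derived from a binarized structural adjacency.

Three nodal metrics (degree, Watts-Strogatz local clustering, local
efficiency) plus a latent-space cluster id used for a homophily term.
The latent construction -- classical MDS of geodesic distances followed by
k-means -- is isolated in :func:`latent_clusters` so it can be swapped.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .graph_core import BrainGraph

__all__ = ["structural_metrics", "latent_clusters", "attach_structural"]


def structural_metrics(s: BrainGraph) -> pd.DataFrame:
    """Degree, local clustering, and local efficiency for every node.

    Clustering is the fraction of a node's neighbor pairs that are
    themselves connected; local efficiency is the mean inverse shortest
    path length between neighbor pairs within the induced neighbor
    subgraph.  Both are 0 for nodes of degree < 2.
    """
    gx = nx.from_numpy_array(s.adjacency)
    deg = dict(gx.degree())
    clus = nx.clustering(gx)
    eff = {}
    for v in gx.nodes:
        nbrs = list(gx.neighbors(v))
        if len(nbrs) < 2:
            eff[v] = 0.0
        else:
            eff[v] = nx.global_efficiency(gx.subgraph(nbrs))
    n = s.n_nodes
    return pd.DataFrame(
        {
            "struct_degree": [float(deg[v]) for v in range(n)],
            "struct_clustering": [float(clus[v]) for v in range(n)],
            "struct_efficiency": [float(eff[v]) for v in range(n)],
        }
    )


def _classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix."""
    d2 = dist**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w_pos = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_pos)


def latent_clusters(
    s: BrainGraph, k: int | str = "auto", seed: int = 0
) -> np.ndarray:
    """Cluster nodes in a 2-D latent embedding of geodesic distances.

    Disconnected pairs get a finite surrogate distance (max finite + 1) so
    every node receives a cluster.  When ``k="auto"`` the cluster count is
    chosen by silhouette over 2..6.  Deterministic under a fixed seed.
    """
    n = s.n_nodes
    if k != "auto":
        k = int(k)
        if n < k:
            raise ValueError(f"cannot form {k} clusters from {n} nodes")
        if k == 1:
            return np.zeros(n, dtype=np.int64)
    dist = shortest_path(s.adjacency.astype(float), method="D", unweighted=True)
    finite = dist[np.isfinite(dist)]
    cap = finite.max() + 1.0 if finite.size else 1.0
    dist = np.where(np.isfinite(dist), dist, cap)
    emb = _classical_mds(dist, n_components=2)
    if k == "auto":
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            lab = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(emb)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(emb, lab)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb).astype(
        np.int64
    )


def attach_structural(
    attrs_table: pd.DataFrame,
    s: BrainGraph,
    k: int | str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Return a copy of the attribute table with structural columns added."""
    if len(attrs_table) != s.n_nodes:
        raise ValueError("attribute table and structural graph size mismatch")
    out = attrs_table.reset_index(drop=True).copy()
    metrics = structural_metrics(s)
    for col in metrics.columns:
        out[col] = metrics[col]
    out["latent_cluster"] = latent_clusters(s, k=k, seed=seed)
    return out
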