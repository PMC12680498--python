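"""Shared-nearest-neighbor graph clustering of cells.

Cells are connected in a Euclidean KNN graph on their PC scores; edges are
re-weighted by the Jaccard overlap of the two cells' neighbor sets and
pruned below 1/15, and the resulting weighted graph is partitioned by
seeded Leiden modularity optimization at the configured resolution
(0.4 in the study).  Labels are 0..C-1 in decreasing cluster size.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

__all__ = ["SNNLeiden", "cluster_cells", "snn_graph"]


def snn_graph(
    scores: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor adjacency (no self loops).

    Neighbor sets include the cell itself (size ``k_neighbors``); the edge
    weight between two cells is |A∩B| / |A∪B| of their neighbor sets, and
    weights below ``prune`` are dropped.
    """
    n = scores.shape[0]
    k = min(k_neighbors, n)
    if n == 1 or k == 1:
        return sp.csr_matrix((n, n))
    # sklearn's self-excluding query gives k-1 neighbors; the cell itself
    # completes the size-k neighbor set
    nn = NearestNeighbors(n_neighbors=k - 1).fit(scores)
    idx = nn.kneighbors(return_distance=False)
    idx = np.hstack([np.arange(n)[:, None], idx])
    rows = np.repeat(np.arange(n), idx.shape[1])
    adj = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n), dtype=float
    )
    inter = (adj @ adj.T).tocoo()
    union = 2 * k - inter.data
    jacc = inter.data / union
    keep = (jacc >= prune) & (inter.row != inter.col)
    return sp.csr_matrix((jacc[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))


class SNNLeiden(ClusterMixin, BaseEstimator):
    """SNN-graph Leiden clustering with a fixed seed.

    Parameters
    ----------
    k_neighbors:
        Neighborhood size for the KNN graph (the cited toolkit's default of
        20); reduced with a warning when there are fewer cells.
    resolution:
        Modularity resolution; larger values give more clusters.
    prune:
        Jaccard cutoff below which SNN edges are discarded.
    """

    def __init__(
        self,
        k_neighbors: int = 20,
        resolution: float = 0.4,
        prune: float = 1 / 15,
        random_state: int = 0,
    ):
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.prune = prune
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.k_neighbors:
            warnings.warn(
                f"only {n} cells for k_neighbors={self.k_neighbors}; reducing k to {n}"
            )
        snn = snn_graph(X, self.k_neighbors, self.prune)
        coo = sp.triu(snn, k=1).tocoo()
        graph = ig.Graph(
            n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
        )
        partition = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=coo.data.tolist(),
            resolution_parameter=self.resolution,
            seed=self.random_state,
            n_iterations=-1,
        )
        raw = np.asarray(partition.membership)
        # relabel 0..C-1 by decreasing cluster size (ties: first occurrence)
        ids, counts = np.unique(raw, return_counts=True)
        order = ids[np.lexsort((ids, -counts))]
        remap = {old: new for new, old in enumerate(order)}
        self.labels_ = np.array([remap[v] for v in raw])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_cells(
    scores: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.4,
    seed: int = 0,
    prune: float = 1 / 15,
) -> np.ndarray:
    """Cluster cells on their PC scores; deterministic under a fixed seed."""
    return SNNLeiden(k_neighbors, resolution, prune, random_state=seed).fit_predict(scores)
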