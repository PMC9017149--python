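"""Clustering and 2-D embedding of a (joint or unimodal) distance matrix.

A shared-nearest-neighbor (SNN) graph is built from the condensed distance
matrix, Louvain community detection partitions it, and t-SNE / UMAP / MDS
run directly on the precomputed distances for visualization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np

from .datamodel import DistanceMatrix

SNN_PRUNE = 1.0 / 15.0  # Jaccard weights below this are dropped


@dataclass
class ClusterResult:
    labels: np.ndarray  # contiguous ints from 0, ordered by cluster size
    resolution: float
    k_neighbors: int
    seed: int


def knn_graph(d: DistanceMatrix, k_neighbors: int = 20) -> igraph.Graph:
    """SNN graph: edges weighted by Jaccard overlap of k-neighbor sets.

    Neighbor sets include the cell itself plus its ``k_neighbors`` nearest
    cells (ties broken by cell index); edges with Jaccard weight below 1/15
    are pruned.  Deterministic given the distances and k.
    """
    n = d.n_cells
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells {n}")
    D = d.to_square()
    np.fill_diagonal(D, -1.0)  # self sorts first, then ties by index (stable)
    order = np.argsort(D, axis=1, kind="stable")
    neighbor_sets = order[:, : k_neighbors + 1]  # includes self

    membership = np.zeros((n, n), dtype=np.int32)
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    membership[rows, neighbor_sets.ravel()] = 1
    shared = membership @ membership.T  # counts of shared neighbors
    size = k_neighbors + 1
    iu, ju = np.triu_indices(n, 1)
    s = shared[iu, ju].astype(float)
    jaccard = s / (2 * size - s)
    keep = jaccard >= SNN_PRUNE
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 0.9,
                    seed: int = 42) -> ClusterResult:
    """Louvain (multilevel modularity) communities at the given resolution.

    Labels are relabeled contiguously from 0 in decreasing cluster size
    (ties by first-member index); the same seed reproduces the same labels.
    """
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution=resolution,
    )
    raw = np.asarray(part.membership)
    ids, counts = np.unique(raw, return_counts=True)
    first_member = np.array([int(np.argmax(raw == i)) for i in ids])
    order = np.lexsort((first_member, -counts))
    remap = {int(ids[pos]): new for new, pos in enumerate(order)}
    labels = np.array([remap[int(v)] for v in raw])
    return ClusterResult(labels=labels, resolution=resolution,
                         k_neighbors=-1, seed=seed)


def embed(d: DistanceMatrix, method: str = "tsne", seed: int = 42) -> np.ndarray:
    """2-D embedding of precomputed distances; reproducible per seed."""
    D = d.to_square()
    n = d.n_cells
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
        ts = TSNE(n_components=2, metric="precomputed", init="random",
                  random_state=seed, perplexity=perplexity)
        return ts.fit_transform(D)
    if method == "umap":
        from umap import UMAP

        um = UMAP(n_components=2, metric="precomputed", random_state=seed,
                  n_neighbors=min(15, n - 1),
                  init="random" if n < 15 else "spectral")
        return np.asarray(um.fit_transform(D))
    if method == "mds":
        from sklearn.manifold import MDS

        mds = MDS(n_components=2, dissimilarity="precomputed",
                  random_state=seed, normalized_stress="auto")
        return mds.fit_transform(D)
    raise ValueError(f"unknown embedding method {method!r}")


def cluster_distance(d: DistanceMatrix, k_neighbors: int = 20,
                     resolution: float = 0.9, seed: int = 42) -> ClusterResult:
    """Convenience: SNN graph + Louvain in one call."""
    result = louvain_cluster(knn_graph(d, k_neighbors), resolution, seed)
    result.k_neighbors = k_neighbors
    return result
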