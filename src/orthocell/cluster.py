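"""kNN-graph community detection, t-SNE visualisation and composition tables.

Cells are connected by the union of their directed k-nearest-neighbour
relations in PC space, edges weighted by the Jaccard overlap of neighbour
sets (each set includes the cell itself, so duplicated points get weight 1).
Communities are found with Leiden modularity optimisation at a configurable
resolution (0.5 by default) and relabelled by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .preprocess import Embedding, NormMatrix

__all__ = [
    "ClusterAssignment",
    "CompositionTable",
    "knn_graph",
    "cluster_graph",
    "embed_tsne",
    "composition",
    "annotate_clusters",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell 0-based cluster ids, contiguous 0..K-1
    resolution: float
    k_neighbors: int
    modularity: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous 0..K-1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class CompositionTable:
    """Cell-type counts and row-stochastic fractions per group."""

    counts: pd.DataFrame  # group x cell-type integer counts
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")


def knn_graph(emb: Embedding | np.ndarray, k: int = 20) -> ig.Graph:
    """Build the Jaccard-weighted union-kNN graph of cells in PC space."""
    from sklearn.neighbors import NearestNeighbors

    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh_sets = []
    for i, row in enumerate(idx):
        s = {int(v) for v in row if v != i}
        while len(s) > k:  # self absent among k+1 (duplicate points): trim
            s.discard(max(s))
        s.add(i)
        neigh_sets.append(frozenset(s))
    edges = {}
    for i, s in enumerate(neigh_sets):
        for j in s:
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if key not in edges:
                a, b = neigh_sets[key[0]], neigh_sets[key[1]]
                edges[key] = len(a & b) / len(a | b)
    g = ig.Graph(n=n, edges=list(edges.keys()), edge_attrs={"weight": list(edges.values())})
    g["k"] = k
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 0.5, seed: int = 0) -> ClusterAssignment:
    """Leiden modularity clustering at the given resolution.

    Labels are relabelled by decreasing cluster size (ties: lower original
    label first), so label 0 is always the largest community.
    """
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    sizes = np.bincount(raw)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[raw]
    mod = graph.modularity(raw, weights=graph.es["weight"] if graph.ecount() else None)
    return ClusterAssignment(labels, resolution, graph["k"] if "k" in graph.attributes() else -1, mod)


def embed_tsne(emb: Embedding | np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE of the PC embedding (visualisation only)."""
    from sklearn.manifold import TSNE

    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb)
    n = coords.shape[0]
    if n < 5:
        raise ValueError(f"t-SNE needs at least 5 cells, got {n}")
    perplexity = min(30.0, (n - 1) / 3.0)
    out = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(coords)
    return np.asarray(out)


def composition(labels, cell_meta: pd.DataFrame, by: str = "sample") -> CompositionTable:
    """Cell-type composition per group (``by`` = a metadata column).

    ``labels`` may be cluster ids or named cell types.  Every cell must have
    non-null group metadata.
    """
    labels = np.asarray(labels)
    if by not in cell_meta.columns:
        raise ValueError(f"cell_meta has no column {by!r}")
    group = cell_meta[by]
    if group.isna().any():
        bad = list(cell_meta.index[group.isna()][:10])
        raise ValueError(f"cells with missing {by!r} metadata: {bad}")
    counts = pd.crosstab(group, pd.Series(labels, index=cell_meta.index, name="celltype"))
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts=counts, fractions=fractions)


def annotate_clusters(nm: NormMatrix, labels, marker_sets: dict[str, list[str]]) -> dict:
    """Name clusters by the marker gene set with maximal mean expression.

    For each cluster the mean log-normalised expression of each set (genes
    absent from the matrix ignored; sets with no present genes skipped) is
    computed, and the cluster is named after the argmax set, ties broken by
    set name.  Mirrors annotation by acknowledged lineage markers.
    """
    labels = np.asarray(labels)
    scores = {}
    for name in sorted(marker_sets):
        present = [g for g in marker_sets[name] if g in nm.gene_index]
        if not present:
            continue
        scores[name] = nm.rows(present).mean(axis=0)  # per-cell mean
    if not scores:
        raise ValueError("no marker-set genes present in the matrix")
    out = {}
    for c in pd.unique(pd.Series(labels).sort_values(kind="stable")):
        mask = labels == c
        best = max(scores, key=lambda s: (scores[s][mask].mean(), ))
        out[c] = best
    return out
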