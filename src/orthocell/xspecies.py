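"""Cross-species cell-type correspondence via ortholog marker intersection.

The core procedure: for each cell type shared between two species, take the
top-50 most enriched (highest fold-change) genes on each side, map the
second species' genes through a one-to-one ortholog table, and intersect;
the union of those per-type intersections defines a shared gene panel.
Pseudobulk (per-cluster mean) profiles of both species over the panel are
stacked, each gene z-scored across the combined clusters, and the clusters
hierarchically clustered with distance = 1 − Pearson correlation (average
linkage).  Each species-A cluster is paired with its maximum-correlation
species-B cluster; species-specific clusters are reported with their best
match rather than suppressed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .markers import top_n_markers
from .preprocess import NormMatrix

__all__ = [
    "OrthologMap",
    "CorrespondenceResult",
    "load_orthologs",
    "shared_marker_set",
    "pseudobulk",
    "correspondence",
]

_HEADER_TOKENS = {
    "gene", "gene_a", "gene_b", "genea", "geneb", "human", "mouse",
    "human_gene", "mouse_gene", "ortholog", "symbol", "a", "b",
}


@dataclass
class OrthologMap:
    """Resolved one-to-one gene pairing between species A and species B."""

    pairs: list[tuple[str, str]]
    n_dropped_multi: int = 0
    n_dropped_absent: int = 0

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("ortholog map is not one-to-one after resolution")

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def restrict(self, genes_a, genes_b) -> "OrthologMap":
        """Drop pairs whose genes are absent from either dataset."""
        ga, gb = set(genes_a), set(genes_b)
        kept = [(a, b) for a, b in self.pairs if a in ga and b in gb]
        return OrthologMap(kept, self.n_dropped_multi, self.n_dropped_absent + len(self.pairs) - len(kept))


def load_orthologs(path: str | Path, genes_a=None, genes_b=None) -> OrthologMap:
    """Read a two-column ortholog TSV and resolve it to one-to-one pairs.

    A header line is tolerated (detected by common column-name tokens).
    Genes appearing more than once in the raw table are dropped entirely —
    only unambiguous pairs survive.  If gene universes are given, pairs
    with genes absent from either dataset are dropped too.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln + 1}: expected at least 2 tab-separated columns")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and all(f.lower() in _HEADER_TOKENS for f in rows[0]):
        rows = rows[1:]
    ca = Counter(a for a, _ in rows)
    cb = Counter(b for _, b in rows)
    kept = [(a, b) for a, b in rows if ca[a] == 1 and cb[b] == 1]
    omap = OrthologMap(kept, n_dropped_multi=len(rows) - len(kept))
    if genes_a is not None or genes_b is not None:
        omap = omap.restrict(genes_a or [p[0] for p in kept], genes_b or [p[1] for p in kept])
    return omap


def shared_marker_set(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    omap: OrthologMap,
    n: int = 50,
    type_pairing: dict | None = None,
) -> list[str]:
    """Union over cell types of the intersected top-n marker genes.

    For each shared type the top-n genes of species A are intersected with
    the ortholog-translated top-n genes of species B.  Types are matched by
    name unless an explicit ``type_pairing`` (A-type → B-type) is supplied.
    Returns species-A gene identifiers, ordered by type (first appearance)
    then gene id.
    """
    if type_pairing is None:
        types_a = list(pd.unique(markers_a["cluster"]))
        shared = [t for t in types_a if t in set(markers_b["cluster"])]
        type_pairing = {t: t for t in shared}
    if not type_pairing:
        raise ValueError("no shared cell types between the two marker tables")
    b_to_a = omap.b_to_a
    out: list[str] = []
    seen = set()
    for ta, tb in type_pairing.items():
        top_a = set(top_n_markers(markers_a, n, cluster=ta))
        top_b = top_n_markers(markers_b, n, cluster=tb)
        top_b_translated = {b_to_a[g] for g in top_b if g in b_to_a}
        for g in sorted(top_a & top_b_translated):
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def pseudobulk(nm: NormMatrix, labels, genes: list[str]) -> pd.DataFrame:
    """Cluster × gene matrix of mean log-normalised expression."""
    labels = np.asarray(labels)
    X = nm.rows(list(genes))
    clusters = pd.unique(pd.Series(labels).sort_values(kind="stable"))
    rows = []
    for c in clusters:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c!r} is empty")
        rows.append(X[:, mask].mean(axis=1))
    return pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"), columns=list(genes))


@dataclass
class CorrespondenceResult:
    shared_genes: list[str]
    pseudobulk: pd.DataFrame  # combined clusters x genes, gene-wise z-scored
    linkage: np.ndarray  # scipy linkage over the combined clusters
    leaf_names: list[str]
    pairing: dict  # A-cluster -> (B-cluster, Pearson similarity)
    similarity_matrix: pd.DataFrame  # A-clusters x B-clusters

    def to_newick(self) -> str:
        """Serialise the dendrogram as a Newick string with leaf names
        (characters reserved by the format are replaced with ``_``)."""
        import re

        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return re.sub(r"[\s,():;]", "_", self.leaf_names[node.id])
            bl_l = max(node.dist - node.left.dist, 0.0)
            bl_r = max(node.dist - node.right.dist, 0.0)
            return f"({rec(node.left)}:{bl_l:.6g},{rec(node.right)}:{bl_r:.6g})"

        return rec(tree) + ";"


def correspondence(
    pb_a: pd.DataFrame,
    pb_b: pd.DataFrame,
    genes: list[str] | None = None,
    prefix_a: str = "A",
    prefix_b: str = "B",
    linkage_method: str = "average",
) -> CorrespondenceResult:
    """Pair clusters across species and build the combined dendrogram.

    Both pseudobulks must be over the same (species-A-identified) gene list;
    translate species B's columns through the ortholog map first.  Gene
    columns are z-scored across the combined clusters; zero-variance columns
    are dropped with a warning.  Similarities are Pearson correlations of
    the scaled profiles; each A-cluster is paired with its argmax B-cluster
    (ties broken by B-cluster order).
    """
    genes = list(genes) if genes is not None else list(pb_a.columns)
    if list(pb_a.columns) != genes or list(pb_b.columns) != genes:
        pb_a = pb_a[genes]
        pb_b = pb_b[genes]
    if len(pb_a) + len(pb_b) < 2:
        raise ValueError("need at least 2 clusters in total")
    names = [f"{prefix_a}:{c}" for c in pb_a.index] + [f"{prefix_b}:{c}" for c in pb_b.index]
    X = np.vstack([pb_a.to_numpy(float), pb_b.to_numpy(float)])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene columns")
    if not keep.any():
        raise ValueError("all gene columns have zero variance across clusters")
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    used_genes = [g for g, k in zip(genes, keep) if k]
    scaled = pd.DataFrame(Xz, index=pd.Index(names, name="cluster"), columns=used_genes)

    dist = pdist(Xz, metric="correlation")  # 1 - Pearson
    Z = hierarchy.linkage(dist, method=linkage_method)

    na = len(pb_a)
    sim = np.corrcoef(Xz)[:na, na:]
    sim_df = pd.DataFrame(sim, index=list(pb_a.index), columns=list(pb_b.index))
    pairing = {}
    for i, a in enumerate(pb_a.index):
        j = int(np.argmax(sim[i]))
        pairing[a] = (pb_b.index[j], float(sim[i, j]))
    return CorrespondenceResult(
        shared_genes=used_genes,
        pseudobulk=scaled,
        linkage=Z,
        leaf_names=names,
        pairing=pairing,
        similarity_matrix=sim_df,
    )
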