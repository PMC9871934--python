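"""Cell and gene quality-control filters and a simplified doublet filter.

Thresholds follow the conventions of droplet scRNA-seq of arterial tissue:
genes detected in fewer than 3 cells are discarded; cells keeping between
100 and 4,000 detected genes (inclusive) and at most 5% mitochondrial counts
are retained; a kNN score against simulated artificial doublets flags the
expected doublet fraction.  Filter order in the pipeline is fixed:
gene filter → cell filter → doublet filter.  No operation mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, read_counts  # noqa: F401  (read_counts re-exported here)

__all__ = [
    "QCConfig",
    "read_counts",
    "filter_genes",
    "filter_cells",
    "detect_doublets",
    "qc_report",
]


@dataclass
class QCConfig:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 100
    max_genes_per_cell: int = 4000
    max_mito_pct: float = 5.0
    mito_gene_prefixes: tuple[str, ...] = ("MT-", "mt-")
    doublet_expected_rate: float = 0.05
    doublet_knn_k: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError(
                f"need 0 <= min_genes_per_cell < max_genes_per_cell, got "
                f"{self.min_genes_per_cell} / {self.max_genes_per_cell}"
            )
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError(f"max_mito_pct must be in [0, 100], got {self.max_mito_pct}")
        if not 0 <= self.doublet_expected_rate < 1:
            raise ValueError("doublet_expected_rate must be in [0, 1)")
        if self.doublet_knn_k < 1:
            raise ValueError("doublet_knn_k must be >= 1")


def _detected_per_gene(cm: CountMatrix) -> np.ndarray:
    """Number of cells in which each gene has a nonzero count."""
    return (cm.counts > 0).sum(axis=1).A.ravel()


def _detected_per_cell(cm: CountMatrix) -> np.ndarray:
    return (cm.counts > 0).sum(axis=0).A.ravel()


def mito_mask(gene_ids: list[str], prefixes: tuple[str, ...] = ("MT-", "mt-")) -> np.ndarray:
    """Boolean mask of mitochondrial genes by symbol prefix."""
    return np.array([any(g.startswith(p) for p in prefixes) for g in gene_ids], dtype=bool)


def pct_mito(cm: CountMatrix, prefixes: tuple[str, ...] = ("MT-", "mt-")) -> np.ndarray:
    """Per-cell percentage of counts on mitochondrial genes (0 for empty cells)."""
    mask = mito_mask(cm.gene_ids, prefixes)
    total = np.asarray(cm.counts.sum(axis=0)).ravel()
    mito = np.asarray(cm.counts[mask, :].sum(axis=0)).ravel() if mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
    return pct


def filter_genes(cm: CountMatrix, cfg: QCConfig | None = None) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` cells."""
    cfg = cfg or QCConfig()
    return cm.subset_genes(_detected_per_gene(cm) >= cfg.min_cells_per_gene)


def filter_cells(cm: CountMatrix, cfg: QCConfig | None = None) -> CountMatrix:
    """Keep cells with detected-gene count in the closed interval
    [min_genes_per_cell, max_genes_per_cell] and mitochondrial percentage
    at most ``max_mito_pct``."""
    cfg = cfg or QCConfig()
    n_genes = _detected_per_cell(cm)
    ok = (
        (n_genes >= cfg.min_genes_per_cell)
        & (n_genes <= cfg.max_genes_per_cell)
        & (pct_mito(cm, cfg.mito_gene_prefixes) <= cfg.max_mito_pct)
    )
    return cm.subset_cells(ok)


def detect_doublets(
    cm: CountMatrix, cfg: QCConfig | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Score cells for being doublets and flag the top expected fraction.

    Artificial doublets (25% of n) are built by pooling the raw counts of
    random cell pairs and normalising the pooled profile like any real
    barcode; real and artificial profiles are embedded together with PCA,
    and each real cell's score is the fraction of artificial profiles among
    its k nearest neighbours.  The top
    ``doublet_expected_rate`` fraction of real cells by score is flagged
    (exactly ``round(rate * n)`` cells; ties broken by cell order).

    Returns ``(scores, flags)`` aligned with ``cm.cell_ids``.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    from .preprocess import lognormalize, select_hvg

    cfg = cfg or QCConfig()
    n = cm.n_cells
    k = cfg.doublet_knn_k
    if n < 2 * k:
        raise ValueError(f"detect_doublets needs at least {2 * k} cells, got {n}")

    rng = np.random.default_rng(seed)
    n_art = max(1, round(0.25 * n))
    i = rng.integers(0, n, size=n_art)
    j = (i + rng.integers(1, n, size=n_art)) % n  # distinct partner
    art_counts = cm.counts[:, i] + cm.counts[:, j]

    nm = lognormalize(cm)
    hvg = select_hvg(nm, n_hvg=min(2000, nm.n_genes))
    rows = [nm.gene_index[g] for g in hvg]
    X = nm.values[rows, :].toarray()  # genes x cells

    art_lib = np.asarray(art_counts.sum(axis=0), dtype=float).ravel()
    art = np.log1p(art_counts[rows, :].toarray() * (nm.scale_factor / art_lib))

    combined = np.hstack([X, art]).T  # observations x genes
    n_pcs = min(30, combined.shape[0] - 1, combined.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=0).fit_transform(combined)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neigh = np.array([[v for v in row if v != c][:k] for c, row in enumerate(idx)])
    scores = (neigh >= n).mean(axis=1)

    n_flag = round(cfg.doublet_expected_rate * n)
    flags = np.zeros(n, dtype=bool)
    if n_flag:
        order = np.argsort(-scores, kind="stable")
        flags[order[:n_flag]] = True
    return scores, flags


def qc_report(cm: CountMatrix, cfg: QCConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-cell QC metrics with kept/flag columns (matrix is not modified).

    Columns: n_genes, n_counts, pct_mito, passes_cell_filter, doublet_score,
    doublet_flag, kept.  Doublet scoring runs on cells passing the cell
    filter (as in the pipeline); other cells get score NaN.
    """
    cfg = cfg or QCConfig()
    n_genes = _detected_per_cell(cm)
    n_counts = np.asarray(cm.counts.sum(axis=0)).ravel()
    pm = pct_mito(cm, cfg.mito_gene_prefixes)
    passes = (
        (n_genes >= cfg.min_genes_per_cell)
        & (n_genes <= cfg.max_genes_per_cell)
        & (pm <= cfg.max_mito_pct)
    )
    score = np.full(cm.n_cells, np.nan)
    flag = np.zeros(cm.n_cells, dtype=bool)
    sub_idx = np.flatnonzero(passes)
    if sub_idx.size >= 2 * cfg.doublet_knn_k:
        s, f = detect_doublets(cm.subset_cells(sub_idx), cfg, seed=seed)
        score[sub_idx] = s
        flag[sub_idx] = f
    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "n_counts": n_counts,
            "pct_mito": pm,
            "passes_cell_filter": passes,
            "doublet_score": score,
            "doublet_flag": flag,
            "kept": passes & ~flag,
        },
        index=pd.Index(cm.cell_ids, name="cell_id"),
    )
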