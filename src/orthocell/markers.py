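"""One-vs-rest marker detection with Wilcoxon rank-sum tests.

For each cluster, every gene expressed in at least ``min_pct`` of the
cluster's cells is tested against all remaining cells on the log-normalised
scale.  Fold changes use the expm1-of-mean convention with a +1 pseudocount,

    avg_log2FC = log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)),

and p-values are Benjamini–Hochberg adjusted within each cluster.  The
scalar test delegates to scipy (exact enumeration for small tie-free
samples, tie- and continuity-corrected normal approximation otherwise);
the matrix path re-implements the asymptotic formula so that all genes of
a cluster are tested from a single ranking pass, and is kept numerically
identical to scipy's asymptotic mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormMatrix

__all__ = [
    "wilcoxon_rank_sum",
    "cluster_markers",
    "all_markers",
    "top_n_markers",
    "dotplot_stats",
]

MARKER_COLUMNS = [
    "cluster",
    "gene",
    "U_statistic",
    "p_value",
    "p_adj_BH",
    "avg_log2FC",
    "pct_in",
    "pct_out",
]


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``
    (midranks for ties).  ``mode='exact'`` enumerates the permutation
    distribution (ties not supported by the exact path); ``'approx'`` uses
    the normal approximation with tie and continuity corrections; ``'auto'``
    picks exact when ``len(x)*len(y) <= 400`` and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be nonempty")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size * y.size <= 400 and not has_ties) else "approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(max(res.pvalue, 0.0), 1.0))


def _rank_sum_matrix(X: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided asymptotic rank-sum test for every row of X.

    Matches ``scipy.stats.mannwhitneyu(method='asymptotic')`` (midranks,
    tie-corrected variance, 0.5 continuity correction).  Returns per-row
    ``(U_in, p)`` where U_in is the statistic of the in-group.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    n1 = int(in_mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(X, axis=1)
    # per-row tie term sum(t^3 - t) over tied groups
    Xs = np.sort(X, axis=1)
    tie_term = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(Xs[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    R1 = ranks[:, in_mask].sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    big = np.maximum(U1, n1 * n2 - U1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (big - mu - 0.5) / sigma
    p = np.where(sigma > 0, 2.0 * stats.norm.sf(z), 1.0)
    return U1, np.clip(p, 0.0, 1.0)


def _log2_fold_change(X: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    m_in = np.expm1(X[:, in_mask]).mean(axis=1)
    m_out = np.expm1(X[:, ~in_mask]).mean(axis=1)
    return np.log2((m_in + 1.0) / (m_out + 1.0))


def _markers_one_cluster(
    X: np.ndarray,
    genes: np.ndarray,
    in_mask: np.ndarray,
    cluster_name,
    min_pct: float,
    only_pos: bool,
    ranks_cache=None,
) -> pd.DataFrame:
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0:
        raise ValueError(f"cluster {cluster_name!r} is empty")
    if n2 == 0:
        raise ValueError(f"cluster {cluster_name!r} has an empty complement")
    pct_in = (X[:, in_mask] > 0).mean(axis=1)
    pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
    lfc = _log2_fold_change(X, in_mask)
    tested = pct_in >= min_pct
    if only_pos:
        tested &= lfc > 0
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    if n1 * n2 <= 400:
        # small clusters: scalar path (exact when tie-free)
        stats_rows = [wilcoxon_rank_sum(X[i, in_mask], X[i, ~in_mask]) for i in idx]
        U = np.array([s[0] for s in stats_rows])
        p = np.array([s[1] for s in stats_rows])
    elif ranks_cache is not None:
        ranks, tie_term = ranks_cache
        U, p = _rank_sum_from_ranks(ranks[idx], tie_term[idx], in_mask)
    else:
        U, p = _rank_sum_matrix(X[idx], in_mask)
    padj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "cluster": cluster_name,
            "gene": genes[idx],
            "U_statistic": U,
            "p_value": p,
            "p_adj_BH": padj,
            "avg_log2FC": lfc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        }
    )
    return out.sort_values(["avg_log2FC", "gene"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def _rank_sum_from_ranks(ranks: np.ndarray, tie_term: np.ndarray, in_mask: np.ndarray):
    """Asymptotic test reusing precomputed whole-population ranks.

    One-vs-rest tests for every cluster share the same pooled ranking, so
    ranks are computed once per gene and reused across clusters.
    """
    n = ranks.shape[1]
    n1 = int(in_mask.sum())
    n2 = n - n1
    R1 = ranks[:, in_mask].sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    big = np.maximum(U1, n1 * n2 - U1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (big - mu - 0.5) / sigma
    p = np.where(sigma > 0, 2.0 * stats.norm.sf(z), 1.0)
    return U1, np.clip(p, 0.0, 1.0)


def _precompute_ranks(X: np.ndarray):
    ranks = stats.rankdata(X, axis=1)
    Xs = np.sort(X, axis=1)
    tie_term = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(Xs[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    return ranks, tie_term


def cluster_markers(
    nm: NormMatrix,
    labels,
    cluster_id,
    min_pct: float = 0.1,
    only_pos: bool = True,
) -> pd.DataFrame:
    """Markers of one cluster vs all other cells.

    Rows are ordered by ``avg_log2FC`` descending with lexicographic gene-id
    tie-break; BH adjustment is across the genes tested for this cluster.
    """
    labels = np.asarray(labels)
    X = nm.values.toarray()
    genes = np.asarray(nm.gene_ids)
    return _markers_one_cluster(X, genes, labels == cluster_id, cluster_id, min_pct, only_pos)


def all_markers(
    nm: NormMatrix,
    labels,
    min_pct: float = 0.1,
    only_pos: bool = True,
) -> pd.DataFrame:
    """Marker tables for every cluster, concatenated.

    The pooled per-gene ranking is computed once and shared across clusters,
    which makes the all-cluster scan only marginally more expensive than a
    single cluster.
    """
    labels = np.asarray(labels)
    X = nm.values.toarray()
    genes = np.asarray(nm.gene_ids)
    cache = _precompute_ranks(X)
    frames = [
        _markers_one_cluster(X, genes, labels == c, c, min_pct, only_pos, ranks_cache=cache)
        for c in pd.unique(pd.Series(labels).sort_values(kind="stable"))
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=MARKER_COLUMNS)


def top_n_markers(mt: pd.DataFrame, n: int, cluster=None) -> list[str]:
    """First ``min(n, rows)`` genes of a (single-cluster) marker table.

    For a multi-cluster table pass ``cluster`` to select the slice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cluster is not None:
        mt = mt[mt["cluster"] == cluster]
    elif mt["cluster"].nunique() > 1:
        raise ValueError("marker table has several clusters; pass cluster=...")
    return mt["gene"].head(n).tolist()


def top_markers_by_cluster(mt: pd.DataFrame, n: int) -> dict:
    """``{cluster: top-n gene list}`` over all clusters present in the table."""
    return {c: top_n_markers(mt, n, cluster=c) for c in pd.unique(mt["cluster"])}


def dotplot_stats(nm: NormMatrix, labels, genes: list[str]) -> pd.DataFrame:
    """Dot-plot summary per (cluster, gene).

    ``fraction_above_mean`` is the share of the cluster's cells whose
    expression exceeds the gene's grand mean over all cells;
    ``mean_expression`` is the cluster mean; ``columnwise_z`` z-scores the
    cluster means per gene across clusters (0 when only one cluster).
    """
    labels = np.asarray(labels)
    X = nm.rows(list(genes))
    grand = X.mean(axis=1)
    clusters = pd.unique(pd.Series(labels).sort_values(kind="stable"))
    rows = []
    means = np.zeros((len(clusters), len(genes)))
    for ci, c in enumerate(clusters):
        sub = X[:, labels == c]
        means[ci] = sub.mean(axis=1)
        for gi, g in enumerate(genes):
            rows.append(
                {
                    "cluster": c,
                    "gene": g,
                    "fraction_above_mean": float((sub[gi] > grand[gi]).mean()),
                    "mean_expression": float(means[ci, gi]),
                }
            )
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    df = pd.DataFrame(rows)
    df["columnwise_z"] = [z[i // len(genes), i % len(genes)] for i in range(len(df))]
    return df
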