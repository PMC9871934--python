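"""Gene-set module scores, group comparisons, and over-representation tests.

Two module-score flavours are provided: the plain per-cell mean of a set's
log-normalised expression (the convention used for calling T-cell immune
states from resident / exhausted / cytotoxic / co-stimulatory panels) and a
control-adjusted variant that subtracts the mean of expression-matched
control genes drawn from equal-frequency average-expression bins (the
AddModuleScore-style score).  Enrichment of a query gene list against a GMT
collection is the upper-tail hypergeometric test with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .markers import wilcoxon_rank_sum
from .preprocess import NormMatrix

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "builtin_tcell_states",
    "module_score",
    "compare_scores",
    "hypergeom_pval",
    "hypergeom_enrich",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (order-preserving) with an optional source path."""

    sets: dict[str, list[str]]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"gene set {name!r}: dropped {len(genes) - len(uniq)} duplicate genes")
            clean[name] = uniq
        self.sets = clean

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln + 1}: GMT lines need name, description, >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, description] + list(genes)) + "\n")


def builtin_tcell_states() -> GeneSetCollection:
    """The bundled T-cell immune-state panels (editable GMT shipped with the
    package).  These are a convenience compilation of commonly used state
    markers, not a reproduction of any published supplementary table."""
    ref = resources.files("orthocell.data").joinpath("tcell_states.gmt")
    with resources.as_file(ref) as p:
        return read_gmt(p)


def module_score(
    nm: NormMatrix,
    gene_set: list[str],
    method: str = "mean",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell score of a gene set.

    ``method='mean'``: arithmetic mean of the set's log-normalised values.
    ``method='control_adjusted'``: mean(set) − mean(control), where each set
    gene contributes ``n_ctrl`` control genes sampled (seeded) from its own
    average-expression bin (``n_bins`` equal-frequency bins over all genes).
    Set genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in gene_set if g in nm.gene_index]
    missing = [g for g in gene_set if g not in nm.gene_index]
    if not present:
        raise ValueError("none of the set's genes are present in the matrix")
    if missing:
        warnings.warn(f"module_score: {len(missing)} set genes absent from matrix")
    set_scores = nm.rows(present).mean(axis=0)
    if method == "mean":
        return set_scores
    if method != "control_adjusted":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    avg = np.asarray(nm.values.mean(axis=1)).ravel()
    order = pd.Series(avg, index=nm.gene_ids)
    bins = pd.qcut(order.rank(method="first"), q=min(n_bins, len(order)), labels=False)
    bin_members = {b: list(order.index[bins == b]) for b in np.unique(bins)}
    ctrl_genes: list[str] = []
    for g in present:
        members = bin_members[bins[g]]
        take = min(n_ctrl, len(members))
        picked = rng.choice(members, size=take, replace=False)
        ctrl_genes.extend(picked.tolist())
    ctrl_scores = nm.rows(ctrl_genes).mean(axis=0)
    return set_scores - ctrl_scores


def compare_scores(scores, group_labels) -> dict:
    """Wilcoxon rank-sum comparison of scores between two groups.

    Returns ``{"U", "p", "groups", "medians"}`` with groups in sorted order.
    """
    scores = np.asarray(scores, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = sorted(pd.unique(group_labels).tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    x = scores[group_labels == groups[0]]
    y = scores[group_labels == groups[1]]
    U, p = wilcoxon_rank_sum(x, y)
    return {
        "U": U,
        "p": p,
        "groups": tuple(groups),
        "medians": (float(np.median(x)), float(np.median(y))),
    }


def hypergeom_pval(overlap: int, universe_size: int, set_size: int, query_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def hypergeom_enrich(
    query: list[str], collection: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Over-representation of a query gene list in each set of a collection.

    Query genes outside the universe are dropped with a warning; set genes
    are likewise intersected with the universe.  BH adjustment is across the
    sets of the collection; rows are sorted by p then set name.
    """
    universe_set = list(dict.fromkeys(universe))
    if not universe_set:
        raise ValueError("empty universe")
    uset = set(universe_set)
    q = [g for g in dict.fromkeys(query) if g in uset]
    outside = len(set(query)) - len(q)
    if outside:
        warnings.warn(f"hypergeom_enrich: dropped {outside} query genes outside the universe")
    if not q:
        raise ValueError("empty query after restriction to the universe")
    qset = set(q)
    rows = []
    for name, genes in collection:
        in_universe = [g for g in genes if g in uset]
        k = len(qset.intersection(in_universe))
        p = hypergeom_pval(k, len(universe_set), len(in_universe), len(q))
        rows.append({"set": name, "set_size": len(in_universe), "overlap": k, "p_value": p})
    df = pd.DataFrame(rows)
    df["p_adj_BH"] = multipletests(df["p_value"], method="fdr_bh")[1] if len(df) else []
    return df.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
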