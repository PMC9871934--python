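"""Log-normalisation, highly-variable-gene selection, scaling and PCA.

Normalisation is the classic counts-per-scale-factor transform,
``ln(1 + count * scale_factor / library_size)`` with scale factor 1e4.
HVG ranking uses binned standardised dispersion: genes are placed into 20
equal-frequency bins by mean log-normalised expression, and ranked by the
within-bin z-score of ``log(variance / mean)``.  Multi-sample harmonisation
is a gene-intersection merge with a sample covariate — deliberately simple;
downstream cross-species correspondence operates on pseudobulk profiles,
which are robust to the absence of anchor-based batch correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "NormMatrix",
    "Embedding",
    "lognormalize",
    "select_hvg",
    "scale_genes",
    "pca",
    "harmonize",
]


@dataclass
class NormMatrix:
    """Log-normalised genes × cells matrix.

    ``values[g, c] = ln(1 + counts[g, c] * scale_factor / library_sizes[c])``;
    sparsity of the counts is preserved (zero stays zero).
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    library_sizes: np.ndarray
    scale_factor: float = 1e4
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def rows(self, genes: list[str]) -> np.ndarray:
        """Dense submatrix for the requested genes (genes × cells)."""
        missing = [g for g in genes if g not in self.gene_index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return self.values[[self.gene_index[g] for g in genes], :].toarray()


@dataclass
class Embedding:
    """PCA (or other) cell embedding: ``coords`` is cells × d."""

    coords: np.ndarray
    explained_variance: np.ndarray
    d: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        self.explained_variance = ev


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """Library-size normalise and log1p-transform a count matrix."""
    lib = np.asarray(cm.counts.sum(axis=0), dtype=float).ravel()
    if np.any(lib == 0):
        bad = [cm.cell_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"zero library size for cells: {bad[:10]}")
    X = cm.counts.tocsc(copy=True).astype(float)
    X = (X @ sp.diags(scale_factor / lib)).tocsc()  # scale columns
    X.data = np.log1p(X.data)
    return NormMatrix(
        X.tocsr(), list(cm.gene_ids), list(cm.cell_ids), lib, scale_factor, cm.cell_meta.copy()
    )


def _gene_moments(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    mean = np.asarray(values.sum(axis=1)).ravel() / n
    sq = np.asarray(values.multiply(values).sum(axis=1)).ravel() / n
    var = np.maximum(sq - mean**2, 0.0)
    return mean, var


def select_hvg(nm: NormMatrix, n_hvg: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by binned standardised dispersion and return the top n.

    Genes are binned (equal-frequency, ``n_bins`` bins) on mean expression;
    the dispersion ``log(var / mean)`` is z-scored within each bin.
    Undefined dispersions (mean or variance 0) rank last.  Ties are broken
    lexicographically by gene id, making the selection fully deterministic.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    mean, var = _gene_moments(nm.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where((mean > 0) & (var > 0), np.log(np.where(mean > 0, var, 1) / np.where(mean > 0, mean, 1)), np.nan)
    df = pd.DataFrame({"gene": nm.gene_ids, "mean": mean, "disp": disp})
    try:
        df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=min(n_bins, len(df)), labels=False)
    except ValueError:  # fewer distinct ranks than bins (tiny matrices)
        df["bin"] = 0
    z = np.full(len(df), -np.inf)
    for _, idx in df.groupby("bin").groups.items():
        d = df.loc[idx, "disp"]
        ok = d.notna()
        if ok.sum() == 0:
            continue
        mu, sd = d[ok].mean(), d[ok].std(ddof=0)
        zz = (d[ok] - mu) / sd if sd > 0 else d[ok] * 0.0
        z[[df.index.get_loc(i) for i in d[ok].index]] = zz.to_numpy()
    df["z"] = z
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(min(n_hvg, len(df))).tolist()


def scale_genes(nm: NormMatrix, genes: list[str], clip: float = 10.0) -> np.ndarray:
    """Z-score each gene row to mean 0 / unit variance, clipped to ±clip.

    Zero-variance genes become all-zero rows.  Returns a dense genes × cells
    array aligned with ``genes``.
    """
    X = nm.rows(genes)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(out, -clip, clip)


def pca(scaled: np.ndarray, n_components: int = 30, seed: int = 0) -> Embedding:
    """Principal components of cells from a scaled genes × cells matrix.

    Exact (full SVD) solver; deterministic up to component sign, which is
    fixed by scikit-learn's sign convention.  If the input has fewer
    dimensions than requested the embedding is padded with zero-variance
    components and a warning is issued.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(scaled, dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    r = min(n_components, n_cells, n_genes)
    if r < n_components:
        warnings.warn(
            f"requested {n_components} components but input supports only {r}; padding with zeros"
        )
    model = PCA(n_components=r, svd_solver="full", random_state=seed)
    coords = model.fit_transform(X)
    ev = model.explained_variance_
    if r < n_components:
        coords = np.hstack([coords, np.zeros((n_cells, n_components - r))])
        ev = np.concatenate([ev, np.zeros(n_components - r)])
    return Embedding(coords=coords, explained_variance=ev, d=n_components)


def harmonize(per_sample: list[NormMatrix]) -> NormMatrix:
    """Merge normalised samples on their common gene set.

    Genes are intersected (ordered as in the first sample), matrices
    concatenated, and a ``sample`` covariate attached for downstream use.
    An empty gene intersection is an error.  With one sample this is the
    identity apart from metadata normalisation.
    """
    if not per_sample:
        raise ValueError("harmonize: no samples given")
    common = set(per_sample[0].gene_ids)
    for nm in per_sample[1:]:
        common &= set(nm.gene_ids)
    if not common:
        raise ValueError("harmonize: empty gene intersection across samples")
    genes = [g for g in per_sample[0].gene_ids if g in common]
    mats, metas, libs, cells = [], [], [], []
    for i, nm in enumerate(per_sample):
        rows = [nm.gene_index[g] for g in genes]
        mats.append(nm.values[rows, :])
        meta = nm.cell_meta.copy()
        if "sample" not in meta.columns:
            meta["sample"] = f"sample{i}"
        metas.append(meta)
        libs.append(nm.library_sizes)
        cells += nm.cell_ids
    if len(set(cells)) != len(cells):
        raise ValueError("harmonize: duplicate cell ids across samples")
    return NormMatrix(
        sp.hstack(mats).tocsr(),
        genes,
        cells,
        np.concatenate(libs),
        per_sample[0].scale_factor,
        pd.concat(metas),
    )
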