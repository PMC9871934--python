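"""Count-matrix container and 10x-style I/O.

The on-disk formats are the two that aneurysm scRNA-seq depositions use:
a MatrixMarket triplet directory (``matrix.mtx[.gz]`` plus
``features.tsv``/``genes.tsv`` and ``barcodes.tsv``, optionally gzipped)
and a dense CSV with genes as rows and cells as columns.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "FormatError", "read_counts", "write_counts"]

#: metadata columns carried with every cell
META_COLUMNS = ("sample", "species", "segment", "condition")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def _dedup(ids: list[str]) -> list[str]:
    """De-duplicate identifiers by suffixing ``.1``, ``.2``, ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    for x in ids:
        k = seen.get(x, 0)
        out.append(x if k == 0 else f"{x}.{k}")
        seen[x] = k + 1
    return out


@dataclass
class CountMatrix:
    """Sparse genes × cells integer count matrix with identifiers and metadata.

    Attributes
    ----------
    counts
        CSR matrix of shape (n_genes, n_cells), non-negative integers.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    cell_meta
        Per-cell table indexed by ``cell_ids``; by convention carries the
        columns ``sample``, ``species``, ``segment`` and ``condition``.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene identifiers are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell identifiers are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count entries")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise FormatError("non-integer count entries")
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(), list(self.gene_ids), list(self.cell_ids), self.cell_meta.copy()
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to a boolean/index gene mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.counts[keep, :],
            [self.gene_ids[i] for i in keep],
            list(self.cell_ids),
            self.cell_meta.copy(),
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.counts[:, keep],
            list(self.gene_ids),
            [self.cell_ids[i] for i in keep],
            self.cell_meta.iloc[keep].copy(),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells × genes) if available."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_tsv_column(path: Path, col: int = 0) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[col] for line in fh if line.strip()]


def _find(dirpath: Path, stems: tuple[str, ...]) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dirpath / f"{stem}{suffix}"
            if p.exists():
                return p
    return None


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from a 10x MTX triplet directory or a dense CSV.

    Identifiers are de-duplicated by suffixing ``.1``, ``.2``, ...; the
    orientation is normalised to genes × cells.  If the directory contains a
    ``cell_meta.csv`` it is attached as per-cell metadata.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise FormatError(f"cannot read counts from {path}: expected a directory or .csv file")


def _read_mtx_dir(dirpath: Path) -> CountMatrix:
    mtx = _find(dirpath, ("matrix.mtx",))
    feat = _find(dirpath, ("features.tsv", "genes.tsv"))
    barc = _find(dirpath, ("barcodes.tsv",))
    if mtx is None or feat is None or barc is None:
        raise FormatError(f"{dirpath}: missing matrix.mtx / features.tsv / barcodes.tsv")
    mat = scipy.io.mmread(str(mtx))
    genes = _dedup(_read_tsv_column(feat))
    cells = _dedup(_read_tsv_column(barc))
    if mat.shape == (len(genes), len(cells)):
        counts = sp.csr_matrix(mat)
    elif mat.shape == (len(cells), len(genes)):
        counts = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"{dirpath}: MTX shape {mat.shape} does not match "
            f"{len(genes)} features / {len(cells)} barcodes"
        )
    if counts.nnz and np.any(counts.data != np.round(counts.data)):
        raise FormatError(f"{dirpath}: non-integer entries in matrix.mtx")
    meta_path = dirpath / "cell_meta.csv"
    meta = pd.DataFrame()
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
    return CountMatrix(counts, genes, cells, meta)


def _read_csv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
        raise FormatError(f"{path}: non-integer entries")
    genes = _dedup([str(g) for g in df.index])
    cells = _dedup([str(c) for c in df.columns])
    return CountMatrix(sp.csr_matrix(vals.astype(np.int64)), genes, cells)


def write_counts(cm: CountMatrix, dirpath: str | Path) -> Path:
    """Write a MTX triplet (plus ``cell_meta.csv``) readable by :func:`read_counts`."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    (dirpath / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in cm.gene_ids))
    (dirpath / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.cell_ids))
    cm.cell_meta.to_csv(dirpath / "cell_meta.csv")
    return dirpath
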