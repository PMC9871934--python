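"""Two-species synthetic scRNA-seq generator with planted ground truth.

The generator emulates the statistical structure of a paired human/mouse
aortic-aneurysm experiment: two species share a panel of orthologous
cell-type programs (smooth muscle, endothelium, fibroblasts, macrophages,
T cells, ...), each species additionally carries private cell types, disease
shifts the composition (SMC depletion, immune expansion) rather than the
per-gene programs, a small block of mitochondrial genes contributes a
controlled share of each cell's counts, and a fraction of barcodes are
doublets formed by summing two cells.

Counts are negative binomial with a mean/dispersion parameterisation,
``Var = mu + mu^2 / dispersion`` — the standard overdispersed model for UMI
counts.  Everything is driven by a single integer seed and reruns are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_counts

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_two_species", "write_dataset"]

_BASE_TYPES = ["SMC", "EC", "Fibroblast", "Macrophage", "TCell"]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class GeneratorConfig:
    """Parameters of the two-species simulation.

    The defaults define a small but realistic study: 5 shared aortic cell
    types plus one species-private type each, two conditions (control vs
    aneurysm) with SMC depletion and immune expansion in disease, 1,000
    orthologous genes of which 25 per type are markers elevated 4-fold,
    13 mitochondrial genes carrying ~3% of counts, and 5% doublets.
    """

    n_celltypes: int = 5  # shared (homologous) cell types
    n_private_celltypes: int = 1  # species-specific types per species
    cells_per_type_per_condition: dict[str, int] = field(
        default_factory=lambda: {"control": 100, "aneurysm": 100}
    )
    n_ortholog_genes: int = 1000
    n_species_specific_genes: int = 100
    n_marker_genes_per_type: int = 25
    marker_fold_change: float = 4.0
    baseline_mean: float = 2.0
    nb_dispersion: float = 1.0
    mito_gene_count: int = 13
    mito_mean_pct: float = 3.0
    doublet_rate: float = 0.05
    condition_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "SMC": {"aneurysm": 0.4},
            "Macrophage": {"aneurysm": 2.0},
            "TCell": {"aneurysm": 2.0},
        }
    )
    species_names: tuple[str, str] = ("human", "mouse")
    seed: int = 0

    def validate(self) -> None:
        pos_int = {
            "n_celltypes": self.n_celltypes,
            "n_ortholog_genes": self.n_ortholog_genes,
            "n_marker_genes_per_type": self.n_marker_genes_per_type,
        }
        for name, v in pos_int.items():
            if int(v) != v or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v}")
        for name, v in (
            ("n_private_celltypes", self.n_private_celltypes),
            ("n_species_specific_genes", self.n_species_specific_genes),
            ("mito_gene_count", self.mito_gene_count),
        ):
            if int(v) != v or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v}")
        for name, v in (
            ("marker_fold_change", self.marker_fold_change),
            ("baseline_mean", self.baseline_mean),
            ("nb_dispersion", self.nb_dispersion),
        ):
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if not 0 < self.mito_mean_pct < 100:
            raise ConfigError(f"mito_mean_pct must be in (0, 100), got {self.mito_mean_pct}")
        if not 0 <= self.doublet_rate < 1:
            raise ConfigError(f"doublet_rate must be in [0, 1), got {self.doublet_rate}")
        if not self.cells_per_type_per_condition:
            raise ConfigError("cells_per_type_per_condition must name at least one condition")
        for cond, n in self.cells_per_type_per_condition.items():
            if int(n) != n or n <= 0:
                raise ConfigError(f"cells_per_type_per_condition[{cond!r}] must be positive, got {n}")
        for t, shifts in self.condition_shift.items():
            for cond, m in shifts.items():
                if not m > 0:
                    raise ConfigError(f"condition_shift[{t!r}][{cond!r}] must be > 0, got {m}")
        if self.n_celltypes * self.n_marker_genes_per_type > self.n_ortholog_genes:
            raise ConfigError(
                "n_ortholog_genes too small: need at least "
                f"{self.n_celltypes * self.n_marker_genes_per_type} for the planted markers"
            )
        if self.n_private_celltypes * self.n_marker_genes_per_type > self.n_species_specific_genes and self.n_private_celltypes:
            raise ConfigError(
                "n_species_specific_genes too small for the private-type markers"
            )

    @property
    def shared_types(self) -> list[str]:
        names = list(_BASE_TYPES[: self.n_celltypes])
        names += [f"Type{i}" for i in range(len(names), self.n_celltypes)]
        return names

    def private_types(self, species: str) -> list[str]:
        return [f"{species}_private{j}" for j in range(self.n_private_celltypes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth used as the oracle in tests.

    ``cell_labels`` maps every barcode (both species) to its cell type —
    doublet barcodes carry the label of their first parent; ``homology`` is a
    bijection between shared species-A and species-B type names;
    ``planted_markers`` lists each type's elevated genes in that species'
    own identifiers; ``ortholog_map`` pairs species-A with species-B gene ids.
    """

    cell_labels: dict[str, str]
    homology: dict[str, str]
    planted_markers: dict[str, list[str]]
    doublet_flags: dict[str, bool]
    ortholog_map: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cell_labels": self.cell_labels,
                    "homology": self.homology,
                    "planted_markers": self.planted_markers,
                    "doublet_flags": self.doublet_flags,
                    "ortholog_map": [list(p) for p in self.ortholog_map],
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["ortholog_map"] = [tuple(p) for p in d["ortholog_map"]]
        return cls(**d)


def _gene_ids(cfg: GeneratorConfig, species_idx: int) -> tuple[list[str], slice, slice, slice]:
    """Gene identifiers for one species: orthologs, private genes, mito genes.

    Species A uses upper-case symbols, species B lower-case — mirroring the
    human/mouse symbol convention — so ``GENEk`` is orthologous to ``genek``.
    """
    n_orth, n_spec, n_mito = (
        cfg.n_ortholog_genes,
        cfg.n_species_specific_genes,
        cfg.mito_gene_count,
    )
    if species_idx == 0:
        orth = [f"GENE{k + 1}" for k in range(n_orth)]
        spec = [f"SPECA{k + 1}" for k in range(n_spec)]
        mito = [f"MT-G{k + 1}" for k in range(n_mito)]
    else:
        orth = [f"gene{k + 1}" for k in range(n_orth)]
        spec = [f"specb{k + 1}" for k in range(n_spec)]
        mito = [f"mt-g{k + 1}" for k in range(n_mito)]
    ids = orth + spec + mito
    return ids, slice(0, n_orth), slice(n_orth, n_orth + n_spec), slice(n_orth + n_spec, len(ids))


def _type_mean_profiles(cfg: GeneratorConfig, species_idx: int):
    """Per-type mean expression vectors and per-type marker gene lists."""
    ids, orth_sl, spec_sl, mito_sl = _gene_ids(cfg, species_idx)
    n_genes = len(ids)
    m = cfg.n_marker_genes_per_type
    types = cfg.shared_types + cfg.private_types(cfg.species_names[species_idx])
    profiles: dict[str, np.ndarray] = {}
    markers: dict[str, list[str]] = {}
    for i, t in enumerate(types):
        mu = np.full(n_genes, cfg.baseline_mean)
        if i < cfg.n_celltypes:  # shared program: markers drawn from orthologs
            lo = orth_sl.start + i * m
        else:  # private program: markers from species-specific genes
            lo = spec_sl.start + (i - cfg.n_celltypes) * m
        mu[lo : lo + m] *= cfg.marker_fold_change
        # mito genes carry mito_mean_pct of this type's counts in expectation
        nonmito_total = mu[: mito_sl.start].sum()
        if cfg.mito_gene_count:
            mito_total = cfg.mito_mean_pct / (100.0 - cfg.mito_mean_pct) * nonmito_total
            mu[mito_sl] = mito_total / cfg.mito_gene_count
        profiles[t] = mu
        markers[t] = [ids[j] for j in range(lo, lo + m)]
    return ids, profiles, markers


def _simulate_species(cfg: GeneratorConfig, species_idx: int, rng: np.random.Generator):
    species = cfg.species_names[species_idx]
    ids, profiles, markers = _type_mean_profiles(cfg, species_idx)
    theta = cfg.nb_dispersion

    blocks, labels, conds = [], [], []
    for t, mu in profiles.items():
        for cond, base_n in cfg.cells_per_type_per_condition.items():
            mult = cfg.condition_shift.get(t, {}).get(cond, 1.0)
            n = max(1, round(base_n * mult))
            p = theta / (theta + mu)
            blocks.append(rng.negative_binomial(theta, p[:, None], size=(len(ids), n)))
            labels += [t] * n
            conds += [cond] * n
    counts = np.concatenate(blocks, axis=1)
    n_cells = counts.shape[1]

    # doublets: replace round(rate*n) barcode slots with sums of two distinct
    # singlets drawn from the pre-replacement pool
    n_doub = round(cfg.doublet_rate * n_cells)
    doublet = np.zeros(n_cells, dtype=bool)
    if n_doub:
        slots = rng.choice(n_cells, size=n_doub, replace=False)
        singlets = counts.copy()
        for s in slots:
            i, j = rng.choice(n_cells, size=2, replace=False)
            counts[:, s] = singlets[:, i] + singlets[:, j]
            labels[s] = labels[i]
            doublet[s] = True

    cell_ids = [f"{species}-{k:05d}" for k in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample": [f"{species}_{c}" for c in conds],
            "species": species,
            "segment": "thoracic",
            "condition": conds,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(sp.csr_matrix(counts), ids, cell_ids, meta)
    return cm, labels, doublet, markers


def generate_two_species(config: GeneratorConfig):
    """Simulate both species and return ``(cm_a, cm_b, truth)``.

    Deterministic: the same config (including ``seed``) yields bit-identical
    matrices.  Shared cell types use the same type names in both species, and
    their planted markers occupy the same ortholog slots, so homologous
    programs really are orthologous at the gene level.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))

    cm_a, labels_a, doub_a, markers_a = _simulate_species(config, 0, rng_a)
    cm_b, labels_b, doub_b, markers_b = _simulate_species(config, 1, rng_b)

    ids_a, orth_sl, _, _ = _gene_ids(config, 0)
    ids_b, _, _, _ = _gene_ids(config, 1)
    omap = list(zip(ids_a[orth_sl], ids_b[orth_sl]))

    planted = dict(markers_a)
    for t, genes in markers_b.items():
        if t not in planted:  # B-private types; shared types have identical slots
            planted[t] = genes

    truth = SyntheticTruth(
        cell_labels={**dict(zip(cm_a.cell_ids, labels_a)), **dict(zip(cm_b.cell_ids, labels_b))},
        homology={t: t for t in config.shared_types},
        planted_markers=planted,
        doublet_flags={
            **dict(zip(cm_a.cell_ids, (bool(x) for x in doub_a))),
            **dict(zip(cm_b.cell_ids, (bool(x) for x in doub_b))),
        },
        ortholog_map=omap,
    )
    return cm_a, cm_b, truth


def write_dataset(outdir: str | Path, cm_a: CountMatrix, cm_b: CountMatrix, truth: SyntheticTruth) -> Path:
    """Write per-sample MTX triplets, sample metadata, ortholog TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cm in (cm_a, cm_b):
        for sample in pd.unique(cm.cell_meta["sample"]):
            mask = (cm.cell_meta["sample"] == sample).to_numpy()
            sub = cm.subset_cells(mask)
            write_counts(sub, outdir / str(sample))
            first = sub.cell_meta.iloc[0]
            rows.append(
                {
                    "sample": sample,
                    "species": first["species"],
                    "segment": first["segment"],
                    "condition": first["condition"],
                    "n_cells": sub.n_cells,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "samples.csv", index=False)
    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in truth.ortholog_map:
            fh.write(f"{a}\t{b}\n")
    truth.to_json(outdir / "truth.json")
    return outdir
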