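"""End-to-end orchestration: simulate/read → QC → preprocess → cluster →
markers → cross-species correspondence → scores, with a single seed and a
run manifest.

Each stage consumes only prior-stage outputs plus the config; per-stage
seeds are derived as ``seed + stage_index`` so identical configs yield
byte-identical artifacts.  On failure the output directory gains a
``failed`` marker naming the stage; partial outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from importlib.metadata import version as _dist_version

from .cluster import cluster_graph, composition, embed_tsne, knn_graph
from .io import CountMatrix, read_counts
from .markers import all_markers
from .preprocess import harmonize, lognormalize, pca, scale_genes, select_hvg
from .qc import QCConfig, detect_doublets, filter_cells, filter_genes
from .scoring import module_score, read_gmt
from .syndata import GeneratorConfig, SyntheticTruth, generate_two_species, write_dataset
from .xspecies import correspondence, load_orthologs, pseudobulk, shared_marker_set

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("orthocell")

_STAGES = ["simulate", "qc", "preprocess", "cluster", "markers", "xspecies", "score"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full run.

    Either ``simulate`` (generator parameters) or ``inputs`` (mapping
    species → list of sample directories, plus ``orthologs`` TSV path)
    must be provided.
    """

    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    simulate: GeneratorConfig | None = None
    inputs: dict | None = None  # {"species": {name: [sample dirs]}, "orthologs": path}
    n_hvg: int = 2000
    n_pcs: int = 30
    resolution: float = 0.5
    knn_k: int = 20
    top_n_display: int = 5
    top_n_xspecies: int = 50
    scale_factor: float = 1e4
    annotation: str = "truth"  # "truth" | "cluster_id" | path to marker-sets YAML
    gene_sets: str | None = None  # optional GMT for the scoring stage

    def __post_init__(self) -> None:
        for name, lo in (("n_hvg", 1), ("n_pcs", 1), ("knn_k", 1), ("top_n_display", 1), ("top_n_xspecies", 1)):
            if getattr(self, name) < lo:
                raise ValueError(f"{name} must be >= {lo}")
        if self.resolution <= 0 or self.scale_factor <= 0:
            raise ValueError("resolution and scale_factor must be positive")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' or 'inputs'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(d.get("qc"), dict):
            qc_known = {f.name for f in fields(QCConfig)}
            bad = set(d["qc"]) - qc_known
            if bad:
                raise ValueError(f"unknown qc config keys: {sorted(bad)}")
            d["qc"] = QCConfig(**d["qc"])
        if isinstance(d.get("simulate"), dict):
            sim_known = {f.name for f in fields(GeneratorConfig)}
            bad = set(d["simulate"]) - sim_known
            if bad:
                raise ValueError(f"unknown simulate config keys: {sorted(bad)}")
            d["simulate"] = GeneratorConfig(**d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_samples(cm: CountMatrix) -> list[CountMatrix]:
    if "sample" not in cm.cell_meta.columns:
        return [cm]
    return [
        cm.subset_cells((cm.cell_meta["sample"] == s).to_numpy())
        for s in pd.unique(cm.cell_meta["sample"])
    ]


def _qc_species(cm: CountMatrix, cfg: QCConfig, seed: int, outdir: Path, tag: str):
    """Per-sample gene → cell → doublet filtering; returns the merged survivor matrix."""
    kept = []
    attrition = []
    for sub in _split_samples(cm):
        sample = sub.cell_meta["sample"].iloc[0] if "sample" in sub.cell_meta.columns else tag
        before = (sub.n_genes, sub.n_cells)
        sub = filter_cells(filter_genes(sub, cfg), cfg)
        if sub.n_cells >= 2 * cfg.doublet_knn_k:
            _, flags = detect_doublets(sub, cfg, seed=seed)
            sub = sub.subset_cells(~flags)
        attrition.append(
            {"sample": sample, "genes_before": before[0], "cells_before": before[1],
             "genes_after": sub.n_genes, "cells_after": sub.n_cells}
        )
        kept.append(sub)
    pd.DataFrame(attrition).to_csv(outdir / f"qc_attrition_{tag}.csv", index=False)
    return kept


def _annotate(cfg: PipelineConfig, nm, labels, truth: SyntheticTruth | None):
    """Map cluster ids to cell-type names per the configured annotation mode."""
    from .cluster import annotate_clusters

    uniq = np.unique(labels)
    if cfg.annotation == "cluster_id":
        return {c: str(c) for c in uniq}
    if cfg.annotation == "truth":
        if truth is None:
            raise ValueError("annotation='truth' requires a simulated run (truth available)")
        out = {}
        for c in uniq:
            ids = [nm.cell_ids[i] for i in np.flatnonzero(labels == c)]
            types = pd.Series([truth.cell_labels[i] for i in ids])
            out[c] = types.mode().sort_values().iloc[0]
        return out
    sets = yaml.safe_load(Path(cfg.annotation).read_text())
    return annotate_clusters(nm, labels, sets)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write artifacts + ``manifest.json``.

    Returns the manifest dict.  Raises on stage failure after writing a
    ``failed`` marker naming the stage and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest: dict = {
        "package": "orthocell",
        "version": _dist_version("orthocell"),
        "seed": config.seed,
        "stage_seeds": {s: config.seed + i for i, s in enumerate(_STAGES)},
        "stages": {},
        "hashes": {},
    }
    state: dict = {}
    try:
        for i, stage in enumerate(_STAGES):
            t0 = time.time()
            _run_stage(stage, config, config.seed + i, outdir, state, manifest)
            log.info("[%s] done in %.1fs", stage, time.time() - t0)
        for name in ("pairing.csv", "shared_genes.txt", "dendrogram.nwk"):
            p = outdir / name
            if p.exists():
                manifest["hashes"][name] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest
    except Exception as e:
        (outdir / "failed").write_text(f"stage={state.get('stage', '?')}: {e}\n")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_stage(stage, cfg: PipelineConfig, seed: int, outdir: Path, state: dict, manifest: dict):
    state["stage"] = stage
    rec: dict = {}
    if stage == "simulate":
        if cfg.simulate is not None:
            sim = GeneratorConfig(**{**asdict(cfg.simulate), "seed": seed})
            cm_a, cm_b, truth = generate_two_species(sim)
            write_dataset(outdir / "simulate", cm_a, cm_b, truth)
            state.update(species={sim.species_names[0]: cm_a, sim.species_names[1]: cm_b},
                         truth=truth, ortholog_path=outdir / "simulate" / "orthologs.tsv")
            rec = {s: {"genes": m.n_genes, "cells": m.n_cells} for s, m in state["species"].items()}
        else:
            species = {}
            for name, dirs in cfg.inputs["species"].items():
                mats = [read_counts(d) for d in dirs]
                merged = mats[0]
                for extra in mats[1:]:
                    if extra.gene_ids != merged.gene_ids:
                        raise ValueError(f"sample gene lists differ within species {name}")
                    merged = CountMatrix(
                        sp.hstack([merged.counts, extra.counts]).tocsr(),
                        merged.gene_ids,
                        merged.cell_ids + extra.cell_ids,
                        pd.concat([merged.cell_meta, extra.cell_meta]),
                    )
                species[name] = merged
            state.update(species=species, truth=None, ortholog_path=cfg.inputs["orthologs"])
            rec = {s: {"genes": m.n_genes, "cells": m.n_cells} for s, m in species.items()}
    elif stage == "qc":
        state["qc_samples"] = {
            s: _qc_species(cm, cfg.qc, seed, outdir, s) for s, cm in state["species"].items()
        }
        for s, mats in state["qc_samples"].items():
            rec[s] = {"cells_after_qc": sum(m.n_cells for m in mats)}
    elif stage == "preprocess":
        state["norm"], state["emb"], state["hvg"] = {}, {}, {}
        for s, mats in state["qc_samples"].items():
            nm = harmonize([lognormalize(m, cfg.scale_factor) for m in mats])
            hvg = select_hvg(nm, n_hvg=min(cfg.n_hvg, nm.n_genes))
            emb = pca(scale_genes(nm, hvg), n_components=cfg.n_pcs, seed=seed)
            state["norm"][s], state["emb"][s], state["hvg"][s] = nm, emb, hvg
            (outdir / f"hvg_{s}.txt").write_text("\n".join(hvg) + "\n")
            rec[s] = {"genes": nm.n_genes, "cells": nm.n_cells, "hvg": len(hvg)}
    elif stage == "cluster":
        state["labels"], state["tsne"] = {}, {}
        for s, emb in state["emb"].items():
            g = knn_graph(emb, k=cfg.knn_k)
            ca = cluster_graph(g, resolution=cfg.resolution, seed=seed)
            state["labels"][s] = ca
            nm = state["norm"][s]
            coords = embed_tsne(emb, seed=seed)
            state["tsne"][s] = coords
            pd.DataFrame(
                {"cluster": ca.labels, "tsne1": coords[:, 0], "tsne2": coords[:, 1]},
                index=pd.Index(nm.cell_ids, name="cell_id"),
            ).to_csv(outdir / f"clusters_{s}.csv")
            for by in ("sample", "condition"):
                if by in nm.cell_meta.columns:
                    composition(ca.labels, nm.cell_meta, by=by).fractions.to_csv(
                        outdir / f"composition_{s}_{by}.csv"
                    )
            rec[s] = {"n_clusters": ca.n_clusters, "modularity": ca.modularity}
    elif stage == "markers":
        state["marker_tables"], state["typed_labels"] = {}, {}
        for s, ca in state["labels"].items():
            nm = state["norm"][s]
            names = _annotate(cfg, nm, ca.labels, state["truth"])
            typed = np.array([names[c] for c in ca.labels])
            mt = all_markers(nm, typed)
            mt.to_csv(outdir / f"markers_{s}.csv", index=False)
            state["marker_tables"][s], state["typed_labels"][s] = mt, typed
            rec[s] = {"cell_types": sorted(set(typed)), "marker_rows": len(mt)}
    elif stage == "xspecies":
        (sa, sb) = list(state["norm"])[:2]
        omap = load_orthologs(
            state["ortholog_path"],
            genes_a=state["norm"][sa].gene_ids,
            genes_b=state["norm"][sb].gene_ids,
        )
        shared = shared_marker_set(
            state["marker_tables"][sa], state["marker_tables"][sb], omap, n=cfg.top_n_xspecies
        )
        if not shared:
            raise ValueError("empty shared marker set across species")
        a_to_b = omap.a_to_b
        pb_a = pseudobulk(state["norm"][sa], state["typed_labels"][sa], shared)
        pb_b = pseudobulk(state["norm"][sb], state["typed_labels"][sb], [a_to_b[g] for g in shared])
        pb_b.columns = shared
        res = correspondence(pb_a, pb_b, shared, prefix_a=sa, prefix_b=sb)
        state["correspondence"] = res
        (outdir / "shared_genes.txt").write_text("\n".join(shared) + "\n")
        res.similarity_matrix.to_csv(outdir / "similarity.csv")
        pd.DataFrame(
            [(a, b, sim) for a, (b, sim) in res.pairing.items()],
            columns=[f"type_{sa}", f"type_{sb}", "pearson_r"],
        ).to_csv(outdir / "pairing.csv", index=False)
        res.pseudobulk.to_csv(outdir / "scaled_pseudobulk.csv")
        pd.DataFrame(res.linkage, columns=["child1", "child2", "height", "size"]).to_csv(
            outdir / "linkage.csv", index=False
        )
        (outdir / "dendrogram.nwk").write_text(res.to_newick() + "\n")
        rec = {"shared_genes": len(shared), "pairs": {str(a): str(b) for a, (b, _) in res.pairing.items()}}
    elif stage == "score":
        if cfg.gene_sets is None:
            rec = {"skipped": "no gene_sets configured"}
        else:
            coll = read_gmt(cfg.gene_sets)
            for s, nm in state["norm"].items():
                scores = {
                    name: module_score(nm, genes, method="mean")
                    for name, genes in coll
                    if any(g in nm.gene_index for g in genes)
                }
                pd.DataFrame(scores, index=pd.Index(nm.cell_ids, name="cell_id")).to_csv(
                    outdir / f"scores_{s}.csv"
                )
            rec = {"sets": len(coll)}
    manifest["stages"][stage] = rec
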