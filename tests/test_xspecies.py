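import numpy as np
import pandas as pd
import pytest

from orthocell import (
    OrthologMap,
    QCConfig,
    all_markers,
    correspondence,
    detect_doublets,
    filter_cells,
    filter_genes,
    load_orthologs,
    lognormalize,
    pseudobulk,
    shared_marker_set,
)


@pytest.fixture(scope="module")
def two_species_typed(small_data):
    """Both species QC'd and normalised, with truth-typed labels."""
    cm_a, cm_b, truth = small_data
    out = []
    for cm in (cm_a, cm_b):
        cfg = QCConfig()
        cm = filter_cells(filter_genes(cm, cfg), cfg)
        _, flags = detect_doublets(cm, cfg, seed=5)
        cm = cm.subset_cells(~flags)
        nm = lognormalize(cm)
        labels = np.array([truth.cell_labels[c] for c in cm.cell_ids])
        out.append((nm, labels))
    return out[0], out[1], truth


class TestLoadOrthologs:
    def test_simple_pairs(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A1\tb1\nA2\tb2\n")
        omap = load_orthologs(p)
        assert omap.pairs == [("A1", "b1"), ("A2", "b2")]

    def test_header_tolerated(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("human\tmouse\nA1\tb1\n")
        assert load_orthologs(p).pairs == [("A1", "b1")]

    def test_one_to_many_dropped_entirely(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A1\tb1\nA1\tb2\nA3\tb3\n")
        omap = load_orthologs(p)
        assert omap.pairs == [("A3", "b3")]
        assert omap.n_dropped_multi == 2

    def test_single_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A1\nA2\n")
        with pytest.raises(ValueError, match="column"):
            load_orthologs(p)

    def test_absent_genes_dropped_with_universes(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A1\tb1\nA2\tb2\n")
        omap = load_orthologs(p, genes_a=["A1"], genes_b=["b1", "b2"])
        assert omap.pairs == [("A1", "b1")]
        assert omap.n_dropped_absent == 1

    def test_generator_map_is_bijective_and_survives(self, small_data, tmp_path):
        _, _, truth = small_data
        p = tmp_path / "m.tsv"
        p.write_text("gene_a\tgene_b\n" + "".join(f"{a}\t{b}\n" for a, b in truth.ortholog_map))
        omap = load_orthologs(p)
        assert omap.pairs == truth.ortholog_map


class TestSharedMarkerSet:
    def _identity_tables(self):
        rows = []
        for t in ("SMC", "EC"):
            for i in range(5):
                rows.append({"cluster": t, "gene": f"G{t}{i}", "avg_log2FC": 5 - i})
        mt = pd.DataFrame(rows)
        omap = OrthologMap([(g, g.lower()) for g in mt["gene"]])
        mt_b = mt.assign(gene=mt["gene"].str.lower())
        return mt, mt_b, omap

    def test_identity_case_returns_topn(self):
        mt, mt_b, omap = self._identity_tables()
        got = shared_marker_set(mt, mt_b, omap, n=5)
        assert set(got) == set(mt["gene"])

    def test_disjoint_topn_contributes_nothing(self):
        mt, mt_b, omap = self._identity_tables()
        mt_b = mt_b.assign(gene=["x%d" % i for i in range(len(mt_b))])
        omap2 = OrthologMap([(f"Z{i}", f"x{i}") for i in range(len(mt_b))])
        assert shared_marker_set(mt, mt_b, omap2, n=5) == []

    def test_no_shared_types_errors(self):
        mt, mt_b, omap = self._identity_tables()
        mt_b = mt_b.assign(cluster="Other")
        with pytest.raises(ValueError, match="shared"):
            shared_marker_set(mt, mt_b, omap, n=5)

    def test_explicit_type_pairing(self):
        mt, mt_b, omap = self._identity_tables()
        mt_b = mt_b.assign(cluster=mt_b["cluster"].map({"SMC": "Mural", "EC": "Endo"}))
        got = shared_marker_set(mt, mt_b, omap, n=5, type_pairing={"SMC": "Mural"})
        assert set(got) == {f"GSMC{i}" for i in range(5)}

    def test_planted_ortholog_markers_recovered(self, two_species_typed, small_cfg):
        (nm_a, lab_a), (nm_b, lab_b), truth = two_species_typed
        mt_a = all_markers(nm_a, lab_a)
        mt_b = all_markers(nm_b, lab_b)
        omap = OrthologMap(truth.ortholog_map).restrict(nm_a.gene_ids, nm_b.gene_ids)
        shared = set(shared_marker_set(mt_a, mt_b, omap, n=50))
        for t in small_cfg.shared_types:
            planted = set(truth.planted_markers[t])
            assert len(planted & shared) >= 0.8 * len(planted)


class TestPseudobulk:
    def test_single_cell_cluster_is_that_cell(self, two_species_typed):
        (nm, lab), _, _ = two_species_typed
        labels = np.array(["rest"] * nm.n_cells)
        labels[0] = "solo"
        pb = pseudobulk(nm, labels, nm.gene_ids[:20])
        assert np.allclose(pb.loc["solo"], nm.values[:20, 0].toarray().ravel())

    def test_merging_equal_subclusters_averages(self, two_species_typed):
        (nm, lab), _, _ = two_species_typed
        half = nm.n_cells // 2
        labels_fine = np.array(["a"] * half + ["b"] * half + ["c"] * (nm.n_cells - 2 * half))
        genes = nm.gene_ids[:10]
        pb_fine = pseudobulk(nm, labels_fine, genes)
        merged = np.array(["ab"] * (2 * half) + ["c"] * (nm.n_cells - 2 * half))
        pb_merged = pseudobulk(nm, merged, genes)
        assert np.allclose(
            pb_merged.loc["ab"], (pb_fine.loc["a"] + pb_fine.loc["b"]) / 2, atol=1e-12
        )

    def test_matches_naive_groupby_oracle(self, two_species_typed):
        (nm, lab), _, _ = two_species_typed
        genes = nm.gene_ids[:15]
        pb = pseudobulk(nm, lab, genes)
        X = pd.DataFrame(nm.rows(genes).T, columns=genes)
        X["lab"] = lab
        oracle = X.groupby("lab").mean()
        assert np.allclose(pb.sort_index(), oracle.sort_index(), atol=1e-12)


class TestCorrespondence:
    def _pb(self, rng, n_types=4, n_genes=30):
        X = rng.normal(size=(n_types, n_genes))
        return pd.DataFrame(
            X, index=[f"T{i}" for i in range(n_types)], columns=[f"G{j}" for j in range(n_genes)]
        )

    def test_identity_copy_pairs_perfectly(self, rng):
        pb = self._pb(rng)
        res = correspondence(pb, pb.copy(), prefix_a="hs", prefix_b="mm")
        for t in pb.index:
            b, sim = res.pairing[t]
            assert b == t and sim == pytest.approx(1.0)
        # namesake pairs merge before any cross-type merge: the first
        # n_types merges each join an hs leaf with its mm namesake
        n = len(pb)
        first = res.linkage[:n, :2].astype(int)
        for left, right in first:
            assert left < 2 * n and right < 2 * n
            assert res.leaf_names[left].split(":")[1] == res.leaf_names[right].split(":")[1]

    def test_one_cluster_per_species(self, rng):
        pb_a = self._pb(rng, n_types=1)
        pb_b = self._pb(rng, n_types=1)
        pb_b.index = ["U0"]
        res = correspondence(pb_a, pb_b)
        assert len(res.linkage) == 1
        assert list(res.pairing) == ["T0"]

    def test_row_order_invariance(self, rng):
        pb_a, pb_b = self._pb(rng), self._pb(rng)
        res1 = correspondence(pb_a, pb_b)
        res2 = correspondence(pb_a.iloc[::-1], pb_b)
        assert {a: b for a, (b, _) in res1.pairing.items()} == {
            a: b for a, (b, _) in res2.pairing.items()
        }

    def test_columns_scaled_to_unit(self, rng):
        res = correspondence(self._pb(rng), self._pb(rng))
        Z = res.pseudobulk.to_numpy()
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_linkage_heights_monotone(self, rng):
        res = correspondence(self._pb(rng, 6), self._pb(rng, 6))
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_has_all_leaves_and_parses(self, rng):
        import io

        from Bio import Phylo

        res = correspondence(self._pb(rng, 3), self._pb(rng, 3))
        nwk = res.to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == {n.replace(":", "_") for n in res.leaf_names}

    def test_zero_variance_columns_dropped(self, rng):
        pb_a, pb_b = self._pb(rng), self._pb(rng)
        pb_a["Gflat"] = 1.0
        pb_b["Gflat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = correspondence(pb_a, pb_b)
        assert "Gflat" not in res.shared_genes

    def test_too_few_clusters_errors(self, rng):
        pb = self._pb(rng, n_types=1)
        with pytest.raises(ValueError):
            correspondence(pb, pb.iloc[:0])

    def test_recovers_planted_homology(self, two_species_typed, small_cfg):
        (nm_a, lab_a), (nm_b, lab_b), truth = two_species_typed
        mt_a = all_markers(nm_a, lab_a)
        mt_b = all_markers(nm_b, lab_b)
        omap = OrthologMap(truth.ortholog_map).restrict(nm_a.gene_ids, nm_b.gene_ids)
        shared = shared_marker_set(mt_a, mt_b, omap, n=50)
        a2b = omap.a_to_b
        pb_a = pseudobulk(nm_a, lab_a, shared)
        pb_b = pseudobulk(nm_b, lab_b, [a2b[g] for g in shared])
        pb_b.columns = shared
        res = correspondence(pb_a, pb_b, shared, prefix_a="human", prefix_b="mouse")
        homolog_sims = []
        for t in small_cfg.shared_types:
            b, sim = res.pairing[t]
            assert b == truth.homology[t]
            homolog_sims.append(sim)
        # the species-specific type is reported, with lower similarity
        assert "human_private0" in res.pairing
        assert res.pairing["human_private0"][1] < min(homolog_sims)
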