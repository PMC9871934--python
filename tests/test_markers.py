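import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from orthocell import (
    QCConfig,
    all_markers,
    cluster_markers,
    detect_doublets,
    dotplot_stats,
    filter_cells,
    filter_genes,
    lognormalize,
    top_n_markers,
    wilcoxon_rank_sum,
)
from orthocell.markers import _rank_sum_matrix


def enumeration_pvalue(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments
    (tie-free samples only): p = 2*min(P(U<=u), P(U>=u)) capped at 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        us.append(ranks[list(combo)].sum() - nx * (nx + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestWilcoxon:
    def test_separated_triples_exact(self):
        U, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert U == 0 and p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_half_U(self):
        U, _ = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert U == 8.0  # n_x*n_y/2

    def test_exact_matches_enumeration_on_random_pairs(self, rng):
        for _ in range(200):
            nx, ny = rng.integers(3, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_pvalue(x, y), abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=10),
        st.lists(st.integers(0, 8), min_size=2, max_size=10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_U_sum(self, xs, ys):
        Uxy, pxy = wilcoxon_rank_sum(xs, ys)
        Uyx, pyx = wilcoxon_rank_sum(ys, xs)
        assert Uxy + Uyx == len(xs) * len(ys)
        assert pxy == pytest.approx(pyx, abs=1e-12)

    def test_vectorised_path_equals_scipy_asymptotic(self, rng):
        X = rng.negative_binomial(1, 0.4, size=(40, 70)).astype(float)
        mask = np.zeros(70, bool)
        mask[:25] = True
        U, p = _rank_sum_matrix(X, mask)
        for i in range(X.shape[0]):
            r = stats.mannwhitneyu(
                X[i, mask], X[i, ~mask], alternative="two-sided", method="asymptotic"
            )
            assert U[i] == pytest.approx(r.statistic, abs=1e-9)
            assert p[i] == pytest.approx(r.pvalue, abs=1e-12)

    def test_null_type_one_error_calibrated(self):
        """At alpha=0.05 the asymptotic test's null rejection rate over NB
        draws (n=30 per side) stays within [0.03, 0.07]."""
        rng = np.random.default_rng(314)
        n_sims = 500
        rej = 0
        for _ in range(n_sims):
            x = rng.negative_binomial(1, 0.4, size=30).astype(float)
            y = rng.negative_binomial(1, 0.4, size=30).astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            rej += p < 0.05
        assert 0.03 <= rej / n_sims <= 0.07


@pytest.fixture(scope="module")
def typed_norm(small_data):
    cm, _, truth = small_data
    cfg = QCConfig()
    cm = filter_cells(filter_genes(cm, cfg), cfg)
    _, flags = detect_doublets(cm, cfg, seed=5)
    cm = cm.subset_cells(~flags)
    nm = lognormalize(cm)
    labels = np.array([truth.cell_labels[c] for c in cm.cell_ids])
    return nm, labels, truth


class TestClusterMarkers:
    def test_planted_markers_rank_high(self, typed_norm):
        nm, labels, truth = typed_norm
        mt = cluster_markers(nm, labels, "SMC")
        planted = [g for g in truth.planted_markers["SMC"] if g in nm.gene_index]
        found = mt[mt["gene"].isin(planted)]
        assert len(found) >= 0.9 * len(planted)
        assert (found["avg_log2FC"] > 0).all()
        assert (found["p_adj_BH"] < 0.05).all()
        # ordered by fold change descending
        assert (mt["avg_log2FC"].diff().dropna() <= 1e-12).all()

    def test_null_gene_rarely_significant(self):
        """A gene identically distributed in and out of the cluster stays
        non-significant with |log2FC| < 0.1 in >=90% of replicates."""
        import scipy.sparse as sp

        from orthocell import CountMatrix

        rng = np.random.default_rng(555)
        hits = 0
        n_rep = 100
        n_side = 5000  # the +-0.1 log2FC band needs this much averaging
        for _ in range(n_rep):
            counts = rng.negative_binomial(1, 1 / 3, size=(30, 2 * n_side))
            cm = CountMatrix(
                sp.csr_matrix(counts),
                [f"G{i}" for i in range(30)],
                [f"C{j}" for j in range(2 * n_side)],
            )
            nm = lognormalize(cm)
            labels = np.array(["in"] * n_side + ["out"] * n_side)
            mt = cluster_markers(nm, labels, "in", only_pos=False)
            row = mt[mt["gene"] == "G0"]
            if len(row) == 1:
                ok = abs(row["avg_log2FC"].iloc[0]) < 0.1 and row["p_value"].iloc[0] > 0.05
            else:
                ok = True  # filtered out: not called a marker
            hits += ok
        assert hits >= 0.9 * n_rep

    def test_min_pct_prefilter(self, typed_norm):
        nm, labels, _ = typed_norm
        mt = cluster_markers(nm, labels, "SMC", min_pct=0.1)
        assert (mt["pct_in"] >= 0.1).all()

    def test_empty_complement_errors(self, typed_norm):
        nm, labels, _ = typed_norm
        with pytest.raises(ValueError):
            cluster_markers(nm, np.full(len(labels), "T"), "T")

    def test_bh_monotone_within_cluster(self, typed_norm):
        nm, labels, _ = typed_norm
        mt = cluster_markers(nm, labels, "EC", only_pos=False).sort_values("p_value")
        assert (mt["p_adj_BH"].diff().dropna() >= -1e-12).all()
        assert (mt["p_adj_BH"] >= mt["p_value"] - 1e-12).all()


class TestTopN:
    def test_truncation(self, typed_norm):
        nm, labels, _ = typed_norm
        mt = cluster_markers(nm, labels, "SMC").head(3)
        assert len(top_n_markers(mt, 5)) == 3

    def test_default_top50_for_cross_species(self, typed_norm):
        nm, labels, _ = typed_norm
        mt = cluster_markers(nm, labels, "SMC")
        if len(mt) >= 50:
            assert len(top_n_markers(mt, 50)) == 50

    def test_tie_break_lexicographic(self):
        import pandas as pd

        mt = pd.DataFrame(
            {"cluster": ["c"] * 3, "gene": ["B", "A", "C"], "avg_log2FC": [1.0, 1.0, 2.0]}
        ).sort_values(["avg_log2FC", "gene"], ascending=[False, True], kind="stable")
        assert top_n_markers(mt, 2) == ["C", "A"]


class TestDotplot:
    def test_matches_two_pass_oracle(self, typed_norm):
        nm, labels, _ = typed_norm
        genes = nm.gene_ids[:5]
        df = dotplot_stats(nm, labels, genes)
        X = nm.rows(genes)
        for _, row in df.iterrows():
            gi = genes.index(row["gene"])
            mask = labels == row["cluster"]
            assert row["fraction_above_mean"] == pytest.approx(
                (X[gi, mask] > X[gi].mean()).mean()
            )
            assert row["mean_expression"] == pytest.approx(X[gi, mask].mean())

    def test_single_cluster_zscores_zero(self, typed_norm):
        nm, labels, _ = typed_norm
        df = dotplot_stats(nm, np.full(len(labels), "all"), nm.gene_ids[:3])
        assert (df["columnwise_z"] == 0).all()

    def test_all_zero_gene(self, rng):
        import scipy.sparse as sp

        from orthocell import CountMatrix

        counts = rng.poisson(2, size=(5, 50))
        counts[3] = 0
        cm = CountMatrix(
            sp.csr_matrix(counts), [f"G{i}" for i in range(5)], [f"C{j}" for j in range(50)]
        )
        nm = lognormalize(cm)
        df = dotplot_stats(nm, ["a"] * 25 + ["b"] * 25, ["G3"])
        assert (df["fraction_above_mean"] == 0).all()

    def test_unknown_gene_errors(self, typed_norm):
        nm, labels, _ = typed_norm
        with pytest.raises(KeyError):
            dotplot_stats(nm, labels, ["NOT_A_GENE"])


def test_all_markers_consistent_with_single_cluster_calls(typed_norm):
    nm, labels, _ = typed_norm
    combined = all_markers(nm, labels)
    single = cluster_markers(nm, labels, "TCell")
    sub = combined[combined["cluster"] == "TCell"].reset_index(drop=True)
    assert sub["gene"].tolist() == single["gene"].tolist()
    assert np.allclose(sub["p_value"], single["p_value"], atol=1e-12)
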