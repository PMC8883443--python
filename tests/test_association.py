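"""Cluster–gene association F-tests, gene-class Fisher tests, overlap test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hoxpos import (
    class_association_fisher,
    cluster_association_ftest,
    ig_cluster_map,
    overlap_hypergeometric,
)
from helpers import enumerate_fisher_two_sided, enumerate_hypergeom_upper_tail


def expr_frame(values, prefix="g"):
    values = np.atleast_2d(values)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"c{i}" for i in range(values.shape[1])],
    )


class TestClusterAssociationFtest:
    def test_constant_gene_f_zero_p_one(self):
        labels = np.repeat([1, 2], 5)
        res = cluster_association_ftest(expr_frame(np.full(10, 2.0)), labels)
        assert res.iloc[0]["f_stat"] == 0.0
        assert res.iloc[0]["p"] == 1.0

    def test_perfect_separation_p_zero(self):
        labels = np.repeat([1, 2], 5)
        values = np.repeat([0.0, 10.0], 5)
        res = cluster_association_ftest(expr_frame(values), labels)
        assert res.iloc[0]["p"] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sum_of_squares_oracle(self, seed):
        """F and p agree with a hand-coded ANOVA decomposition to 1e-10."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, 30)
        while np.bincount(labels, minlength=3).min() < 2:
            labels = rng.integers(0, 3, 30)
        values = rng.normal(0, 1, size=(5, 30))
        res = cluster_association_ftest(expr_frame(values), labels)
        for gi in range(5):
            y = values[gi]
            groups = [y[labels == k] for k in np.unique(labels)]
            grand = y.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            k, n = len(groups), y.size
            f = (ssb / (k - 1)) / (ssw / (n - k))
            p = stats.f.sf(f, k - 1, n - k)
            assert res.iloc[gi]["f_stat"] == pytest.approx(f, abs=1e-10)
            assert res.iloc[gi]["p"] == pytest.approx(p, abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Labels independent of expression give uniform p (KS at α = 0.01)."""
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 4, 100)
        values = rng.normal(0, 1, size=(600, 100))
        res = cluster_association_ftest(expr_frame(values), labels)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_association_ftest(expr_frame(np.zeros(6)), np.ones(6))


class TestClassAssociationFisher:
    def test_matches_enumeration_on_small_universe(self):
        """Class = significant set on a 12-gene universe: exact 2×2 Fisher."""
        genes = [f"g{i}" for i in range(12)]
        res_table = pd.DataFrame(
            {
                "p": [1e-6] * 6 + [0.9] * 6,
                "p_adj": [1e-5] * 6 + [0.9] * 6,
            },
            index=pd.Index(genes, name="gene"),
        )
        cls = set(genes[:6])
        out = class_association_fisher(res_table, {"cls": cls}, alpha=0.05)
        expected = enumerate_fisher_two_sided(6, 0, 0, 6)
        assert out.loc["cls", "fisher_p"] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(15)]
        sig = set(rng.choice(genes, 6, replace=False))
        cls = set(rng.choice(genes, 7, replace=False))
        res_table = pd.DataFrame(
            {
                "p": [1e-6 if g in sig else 0.8 for g in genes],
                "p_adj": [1e-5 if g in sig else 0.9 for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
        out = class_association_fisher(res_table, {"cls": cls}, alpha=0.05)
        a = len(sig & cls)
        b = len(sig - cls)
        c = len(cls - sig)
        d = 15 - a - b - c
        expected = enumerate_fisher_two_sided(a, b, c, d)
        assert out.loc["cls", "fisher_p"] == pytest.approx(expected, rel=1e-9)

    def test_everything_significant_is_degenerate(self):
        genes = [f"g{i}" for i in range(10)]
        res_table = pd.DataFrame(
            {"p": [1e-6] * 10, "p_adj": [1e-5] * 10},
            index=pd.Index(genes, name="gene"),
        )
        out = class_association_fisher(res_table, {"cls": set(genes[:4])}, alpha=1.0)
        assert out.loc["cls", "fisher_p"] == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        res_table = pd.DataFrame(
            {"p": [0.5], "p_adj": [0.5]}, index=pd.Index(["g0"], name="gene")
        )
        with pytest.raises(ValueError):
            class_association_fisher(res_table, {"cls": {"absent"}})


class TestIgClusterMap:
    def test_identical_cells_mean_equals_median(self):
        expr = expr_frame(np.full((2, 6), 3.0), prefix="IG")
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=expr.columns)
        out = ig_cluster_map(expr, labels, ["IG0", "IG1"])
        assert out["mean_expr"].to_numpy() == pytest.approx(3.0)
        assert out["median_expr"].to_numpy() == pytest.approx(3.0)

    def test_empty_ig_set_gives_empty_map(self):
        expr = expr_frame(np.zeros((2, 4)))
        labels = pd.Series([1, 1, 2, 2], index=expr.columns)
        out = ig_cluster_map(expr, labels, [])
        assert out.empty

    def test_unknown_gene_reported_not_fatal(self):
        expr = expr_frame(np.ones((1, 4)), prefix="IG")
        labels = pd.Series([1, 1, 2, 2], index=expr.columns)
        out = ig_cluster_map(expr, labels, ["IG0", "missing"])
        assert out.attrs["missing"] == ["missing"]

    def test_single_cluster_reproduces_grand_means(self, rng):
        expr = expr_frame(rng.normal(0, 1, size=(3, 8)), prefix="IG")
        labels = pd.Series(1, index=expr.columns)
        out = ig_cluster_map(expr, labels, list(expr.index)).set_index("gene")
        for g in expr.index:
            assert out.loc[g, "mean_expr"] == pytest.approx(expr.loc[g].mean())

    def test_linked_gene_elevated_in_its_cluster(self, homeo_sim):
        """Generative oracle: a linked Ig gene's cluster mean ≫ global mean."""
        m, truth = homeo_sim
        from hoxpos import size_factors

        sf = size_factors(m)
        norm = pd.DataFrame(
            np.log1p(m.counts / sf[None, :]), index=m.gene_ids, columns=m.cell_ids
        )
        labels = pd.Series(truth.cluster_labels, index=m.cell_ids)
        ig_genes = m.genes_in_class("Ig-domain")
        out = ig_cluster_map(norm, labels, ig_genes)
        ig_ids = list(ig_genes)
        cluster0_linked = truth.params["linked_ig"][0]
        gene = ig_ids[cluster0_linked[0]]
        sub = out[out["gene"] == gene]
        linked_mean = float(sub.loc[sub["cluster"] == 0, "mean_expr"].iloc[0])
        global_mean = float(norm.loc[gene].mean())
        assert linked_mean >= 1.2 * global_mean

    def test_invariant_to_cell_order(self, rng):
        expr = expr_frame(rng.normal(0, 1, size=(2, 10)), prefix="IG")
        labels = pd.Series(np.repeat([1, 2], 5), index=expr.columns)
        base = ig_cluster_map(expr, labels, list(expr.index))
        perm = rng.permutation(10)
        shuffled = ig_cluster_map(
            expr.iloc[:, perm], labels.iloc[perm], list(expr.index)
        )
        merged = base.merge(shuffled, on=["cluster", "gene"], suffixes=("_a", "_b"))
        assert merged["mean_expr_a"].to_numpy() == pytest.approx(
            merged["mean_expr_b"].to_numpy()
        )


class TestOverlapHypergeometric:
    def test_identical_sets_saturating_universe(self):
        genes = {f"g{i}" for i in range(5)}
        p, k = overlap_hypergeometric(genes, genes, universe_size=5)
        assert p == pytest.approx(1.0)
        assert k == 5

    def test_closed_form_ten_five_five_five(self):
        a = {f"g{i}" for i in range(5)}
        p, k = overlap_hypergeometric(a, a, universe_size=10)
        assert k == 5
        assert p == pytest.approx(1 / 252)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(15)]
        a = set(rng.choice(universe, 6, replace=False))
        b = set(rng.choice(universe, 5, replace=False))
        p, _ = overlap_hypergeometric(a, b, universe_size=15)
        assert p == pytest.approx(
            enumerate_hypergeom_upper_tail(universe, a, b), rel=1e-9
        )

    def test_sets_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_hypergeometric({f"g{i}" for i in range(6)}, set(), universe_size=5)
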