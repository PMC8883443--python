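"""Major clusters, homeodomain-code clusters, subtype scores, depth check."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hoxpos import (
    CountMatrix,
    covariate_check,
    fit_technical_noise,
    homeo_clustering,
    near_binary_matrix,
    scale_expression,
    simulate_homeo_population,
    size_factors,
    subtype_score,
    top_variable_clustering,
)
from hoxpos import test_variable_genes as call_variable_genes


def three_marker_populations(seed=0, cells_per=30):
    """Three populations with disjoint high-expression marker blocks."""
    rng = np.random.default_rng(seed)
    n = 3 * cells_per
    counts = rng.poisson(5, size=(40, n))
    for k in range(3):
        block = slice(k * 10, k * 10 + 10)
        cells = slice(k * cells_per, (k + 1) * cells_per)
        counts[block, cells] = rng.poisson(60, size=(10, cells_per))
    labels = np.repeat(np.arange(3), cells_per)
    m = CountMatrix(
        counts, [f"g{i}" for i in range(40)], [f"c{i}" for i in range(n)]
    )
    return m, labels


class TestTopVariableClustering:
    def test_planted_populations_recovered(self):
        m, truth = three_marker_populations()
        sf = size_factors(m)
        fit = fit_technical_noise(m, sf, min_mean_quantile=0.0)
        hvg = call_variable_genes(m, fit)
        scaled = scale_expression(m, fit)
        labels, panel = top_variable_clustering(scaled, hvg, n_genes=20, n_clusters=3)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(panel) == 20

    def test_single_cluster_single_label(self):
        m, _ = three_marker_populations()
        sf = size_factors(m)
        fit = fit_technical_noise(m, sf, min_mean_quantile=0.0)
        hvg = call_variable_genes(m, fit)
        scaled = scale_expression(m, fit)
        labels, _ = top_variable_clustering(scaled, hvg, n_genes=10, n_clusters=1)
        assert labels.nunique() == 1

    def test_duplicated_cells_comember(self):
        m, _ = three_marker_populations(cells_per=10)
        doubled = CountMatrix(
            np.hstack([m.counts, m.counts]),
            m.gene_ids,
            m.cell_ids + [f"{c}_dup" for c in m.cell_ids],
        )
        sf = size_factors(doubled)
        fit = fit_technical_noise(doubled, sf, min_mean_quantile=0.0)
        hvg = call_variable_genes(doubled, fit)
        scaled = scale_expression(doubled, fit)
        labels, _ = top_variable_clustering(scaled, hvg, n_genes=10, n_clusters=3)
        for c in m.cell_ids:
            assert labels[c] == labels[f"{c}_dup"]


class TestHomeoClustering:
    def test_planted_codes_recovered(self, homeo_sim):
        m, truth = homeo_sim
        sf = size_factors(m)
        nb = near_binary_matrix(m, size_factors=sf)
        panel = m.genes_in_class("homeobox")
        labels = homeo_clustering(nb.loc[panel], n_clusters=6)
        assert adjusted_rand_score(truth.cluster_labels, labels) >= 0.9

    def test_cluster_ids_ordered_by_position(self, homeo_sim):
        m, truth = homeo_sim
        nb = near_binary_matrix(m, size_factors=size_factors(m))
        panel = m.genes_in_class("homeobox")
        pos = pd.Series(truth.positions, index=m.cell_ids)
        labels = homeo_clustering(nb.loc[panel], n_clusters=6, positions=pos)
        mean_pos = pos.groupby(labels).mean()
        assert (mean_pos.sort_index().diff().dropna() > 0).all()

    def test_invariant_to_cell_and_gene_order(self, homeo_sim):
        m, _ = homeo_sim
        nb = near_binary_matrix(m, size_factors=size_factors(m))
        panel = m.genes_in_class("homeobox")
        base = homeo_clustering(nb.loc[panel], n_clusters=6)
        rng = np.random.default_rng(0)
        cells = list(nb.columns)
        rng.shuffle(cells)
        genes = list(panel)
        rng.shuffle(genes)
        shuffled = homeo_clustering(nb.loc[genes, cells], n_clusters=6)
        # same partition content regardless of label numbering
        assert adjusted_rand_score(
            base.reindex(cells), shuffled.reindex(cells)
        ) == pytest.approx(1.0)

    def test_hox_mask_excludes_cells(self, homeo_sim):
        m, _ = homeo_sim
        nb = near_binary_matrix(m, size_factors=size_factors(m))
        panel = m.genes_in_class("homeobox")
        mask = pd.Series(False, index=nb.columns)
        mask.iloc[:10] = True
        labels = homeo_clustering(nb.loc[panel], hox_mask=mask, n_clusters=6)
        assert set(labels.index) == set(nb.columns[10:])

    def test_more_clusters_than_cells_rejected(self, homeo_sim):
        m, _ = homeo_sim
        nb = near_binary_matrix(m, size_factors=size_factors(m))
        with pytest.raises(ValueError):
            homeo_clustering(nb, n_clusters=m.n_cells + 1)


class TestSubtypeScore:
    def test_ubiquitous_marker_contributes_nothing(self):
        counts = np.array([[1, 1, 1, 1], [0, 2, 0, 0]])
        m = CountMatrix(counts, ["everywhere", "ventral"], list("abcd"))
        scores = subtype_score(m, dmn_markers=["everywhere"], vmn_markers=["ventral"])
        assert scores["dmn_score"].to_numpy() == pytest.approx(0.0)

    def test_half_prevalence_marker_scores_ln2(self):
        counts = np.array([[3, 0], [0, 1]])
        m = CountMatrix(counts, ["dorsal", "ventral"], ["A", "B"])
        scores = subtype_score(m, ["dorsal"], ["ventral"])
        assert scores.loc["A", "dmn_score"] == pytest.approx(np.log(2))
        assert scores.loc["A", "call"] == "dMN"
        assert scores.loc["B", "call"] == "vMN"

    def test_tie_is_ambiguous(self):
        counts = np.array([[1, 0], [1, 0]])
        m = CountMatrix(counts, ["dorsal", "ventral"], ["A", "B"])
        scores = subtype_score(m, ["dorsal"], ["ventral"])
        assert (scores["call"] == "ambiguous").all()

    def test_score_monotone_in_observed_markers(self):
        counts = np.array([[1, 1], [0, 1], [1, 0]])
        m = CountMatrix(counts, ["d1", "d2", "ventral"], ["A", "B"])
        one = subtype_score(m, ["d1"], ["ventral"])
        two = subtype_score(m, ["d1", "d2"], ["ventral"])
        assert (two["dmn_score"] >= one["dmn_score"] - 1e-12).all()

    def test_never_observed_marker_warns_and_is_skipped(self):
        counts = np.array([[0, 0], [1, 0]])
        m = CountMatrix(counts, ["ghost", "ventral"], ["A", "B"])
        with pytest.warns(UserWarning, match="never observed"):
            scores = subtype_score(m, ["ghost"], ["ventral"])
        assert scores["dmn_score"].to_numpy() == pytest.approx(0.0)

    def test_planted_exclusive_markers_called_correctly(self):
        rng = np.random.default_rng(3)
        n = 100
        is_dorsal = np.arange(n) < 60
        counts = np.zeros((2, n), dtype=int)
        counts[0, is_dorsal] = rng.poisson(5, 60) + 1
        counts[1, ~is_dorsal] = rng.poisson(5, 40) + 1
        m = CountMatrix(counts, ["dm", "vm"], [f"c{i}" for i in range(n)])
        scores = subtype_score(m, ["dm"], ["vm"])
        assert (scores["call"][is_dorsal] == "dMN").all()
        assert (scores["call"][~is_dorsal] == "vMN").all()


class TestCovariateCheck:
    def test_identical_depth_gives_p_one(self):
        labels = pd.Series([1, 1, 2, 2, 3, 3], index=list("abcdef"))
        res = covariate_check(labels, np.full(6, 100.0))
        assert res["p"].to_numpy() == pytest.approx(1.0)

    def test_depth_driven_cluster_flagged(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(np.repeat([1, 2], 30), index=[f"c{i}" for i in range(60)])
        depth = np.concatenate([rng.poisson(1000, 30), rng.poisson(10000, 30)])
        res = covariate_check(labels, depth.astype(float))
        assert (res["p"] < 1e-6).all()

    def test_independent_depth_rarely_flagged(self, homeo_sim):
        """Depth drawn independently of the clusters is almost never flagged.

        (Total read counts are not a valid null here: clusters with more
        "on" code genes genuinely sequence deeper.)
        """
        m, truth = homeo_sim
        labels = pd.Series(truth.cluster_labels, index=m.cell_ids)
        rng = np.random.default_rng(99)
        depth = pd.Series(rng.lognormal(9, 0.4, m.n_cells), index=m.cell_ids)
        res = covariate_check(labels, depth)
        assert res.attrs["n_below_0.05"] <= 2

    def test_single_cluster_rejected(self):
        labels = pd.Series([1, 1, 1], index=list("abc"))
        with pytest.raises(ValueError):
            covariate_check(labels, np.ones(3))
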