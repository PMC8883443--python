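"""Association between cluster identity and gene / gene-class expression.

Per gene, a one-way ANOVA F-test asks whether expression depends on
homeodomain-code cluster identity (BH-adjusted across genes).  Per gene
class, a 2×2 Fisher exact test asks whether the class is over-represented
among cluster-associated genes, complemented by a two-sided rank-sum test
contrasting the association p-values of class members against other genes.
A hypergeometric overlap test against a fixed gene universe (default
13,920 protein-coding genes) serves externally supplied gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def cluster_association_ftest(
    scaled_expr: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """One-way ANOVA of each gene's expression across cluster labels.

    ``scaled_expr`` is genes × cells; ``labels`` aligns with its columns.
    Returns f_stat, p, p_adj per gene.  Constant genes get F = 0, p = 1;
    perfect separation (no within-cluster variance) gives p → 0.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(scaled_expr.columns).to_numpy()
    labels = np.asarray(labels)
    uniq, inverse = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need ≥ 2 clusters")
    counts = np.bincount(inverse)
    if (counts < 2).any():
        raise ValueError("every cluster needs ≥ 2 cells")
    X = scaled_expr.to_numpy(dtype=float)
    n = X.shape[1]
    grand = X.mean(axis=1, keepdims=True)
    group_sums = np.zeros((X.shape[0], k))
    np.add.at(group_sums.T, inverse, X.T)
    group_means = group_sums / counts[None, :]
    ssb = (counts[None, :] * (group_means - grand) ** 2).sum(axis=1)
    sst = ((X - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where(ssb == 0, 0.0, f)  # constant gene: no between-group signal
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w))
    p = np.where(f == 0, 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"f_stat": f, "p": p, "p_adj": p_adj},
        index=scaled_expr.index.rename("gene"),
    )


def class_association_fisher(
    results: pd.DataFrame,
    class_sets: dict[str, set[str]],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Gene-class enrichment among cluster-associated genes.

    Builds, per class, the 2×2 table (significant at ``alpha`` × in class)
    with a two-sided Fisher exact test, and adds the complementary two-sided
    rank-sum test comparing −log10 association p-values of in-class vs
    out-of-class genes.
    """
    tested = set(results.index)
    pcol = "p_adj" if use_adjusted else "p"
    sig = set(results.index[results[pcol] <= alpha])
    rows = []
    for name, genes in class_sets.items():
        in_class = set(genes) & tested
        if not in_class:
            raise ValueError(f"class {name!r} has no tested genes")
        a = len(sig & in_class)
        b = len(sig - in_class)
        c = len(in_class - sig)
        d = len(tested - in_class - sig)
        odds, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        neglog = -np.log10(np.maximum(results["p"].to_numpy(dtype=float), 1e-300))
        mask = results.index.isin(in_class)
        if mask.all():
            wilcoxon_p = np.nan
        elif np.ptp(neglog) == 0:
            wilcoxon_p = 1.0
        else:
            wilcoxon_p = float(
                stats.mannwhitneyu(
                    neglog[mask], neglog[~mask], alternative="two-sided"
                ).pvalue
            )
        rows.append(
            {
                "class": name,
                "n_class": len(in_class),
                "n_significant": len(sig),
                "overlap": a,
                "odds_ratio": odds,
                "fisher_p": float(fisher_p),
                "wilcoxon_p": wilcoxon_p,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def ig_cluster_map(
    norm_expr: pd.DataFrame,
    labels: pd.Series,
    ig_genes: set[str] | list[str],
    positions: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean and median normalized expression of Ig genes per cluster.

    Rows are (cluster, gene) pairs; clusters are ordered by mean inferred AP
    position when ``positions`` is given, otherwise by label.  Unknown Ig
    gene ids are reported in ``attrs['missing']``, not fatal.
    """
    labels = labels.reindex(norm_expr.columns)
    present = [g for g in ig_genes if g in norm_expr.index]
    missing = sorted(set(ig_genes) - set(present))
    if positions is not None:
        order = positions.reindex(labels.index).groupby(labels).mean().sort_values().index
    else:
        order = sorted(labels.dropna().unique())
    rows = []
    for cluster in order:
        cells = labels.index[labels == cluster]
        block = norm_expr.loc[present, cells]
        for gene in present:
            rows.append(
                {
                    "cluster": cluster,
                    "gene": gene,
                    "mean_expr": float(block.loc[gene].mean()),
                    "median_expr": float(block.loc[gene].median()),
                }
            )
    out = pd.DataFrame(rows, columns=["cluster", "gene", "mean_expr", "median_expr"])
    out.attrs["missing"] = missing
    return out


def overlap_hypergeometric(
    set_a: set[str], set_b: set[str], universe_size: int = 13920
) -> tuple[float, int]:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    Probability of observing at least the actual overlap when |B| genes are
    drawn without replacement from a universe containing |A| marked genes.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("sets cannot exceed the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return p, k
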