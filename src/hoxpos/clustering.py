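"""Cell clustering: major clusters, homeodomain-code clusters, subtype scores.

Major clusters come from ward/Euclidean hierarchical clustering of cells on
the scaled expression of the most variable genes (default 20, cut at 3).
Homeodomain-code clusters use near-binary values of the variable homeobox
genes, with Hox-negative cells excluded, cut at 60 by default (the estimated
number of twit-low cells), and cluster ids are reported in order of mean
inferred AP position.  A rank-sum check verifies clusters are not explained
by sequencing depth.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from .containers import CountMatrix

log = logging.getLogger(__name__)


def _ward_cells(values: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward/Euclidean clustering of rows; returns labels 1..n_clusters."""
    if values.shape[0] < n_clusters:
        raise ValueError("fewer cells than clusters")
    if n_clusters < 1:
        raise ValueError("n_clusters must be ≥ 1")
    if n_clusters == 1:
        return np.ones(values.shape[0], dtype=int)
    Z = linkage(values, method="ward")
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def top_variable_clustering(
    scaled_expr: pd.DataFrame,
    hvg: pd.DataFrame,
    n_genes: int = 20,
    n_clusters: int = 3,
) -> tuple[pd.Series, list[str]]:
    """Cluster cells on the top-variable genes.

    Genes are ranked by the variability test (ascending p, descending CV² on
    ties); cells are clustered on their scaled expression.  Returns per-cell
    labels and the gene panel used.
    """
    ranked = hvg.sort_values(["p", "cv2"], ascending=[True, False])
    panel = [g for g in ranked.index if g in scaled_expr.index][:n_genes]
    if len(panel) < n_genes:
        raise ValueError(f"only {len(panel)} ranked genes available, need {n_genes}")
    values = scaled_expr.loc[panel].to_numpy(dtype=float).T  # cells × genes
    labels = _ward_cells(values, n_clusters)
    return (
        pd.Series(labels, index=scaled_expr.columns, name="major_cluster"),
        panel,
    )


def name_major_clusters(
    m: CountMatrix,
    labels: pd.Series,
    twit_gene: str = "twit",
    vum_markers: tuple[str, ...] = ("Vmat", "Tbh", "dgk", "zfh1"),
) -> dict[int, str]:
    """Name clusters by marker means: VUM by its marker panel, then twit level.

    Returns a mapping cluster id → name; clusters that cannot be named keep
    their integer id as a string.
    """
    names: dict[int, str] = {k: str(k) for k in sorted(labels.unique())}
    cell_idx = {c: i for i, c in enumerate(m.cell_ids)}
    cols = np.array([cell_idx[c] for c in labels.index])
    present_vum = [g for g in vum_markers if g in m.gene_ids]
    if twit_gene not in m.gene_ids or not present_vum:
        return names
    twit = m.counts[m.gene_index([twit_gene])[0], cols].astype(float)
    vum = m.counts[m.gene_index(present_vum), :][:, cols].astype(float).mean(axis=0)
    by_cluster = pd.DataFrame({"twit": twit, "vum": vum, "k": labels.to_numpy()})
    means = by_cluster.groupby("k").mean()
    vum_id = int(means["vum"].idxmax())
    names[vum_id] = "VUM"
    rest = means.drop(index=vum_id).sort_values("twit")
    if len(rest) >= 2:
        names[int(rest.index[0])] = "twit_low"
        names[int(rest.index[-1])] = "twit_high"
    return names


def homeo_clustering(
    nb_expr: pd.DataFrame,
    hox_mask: pd.Series | np.ndarray | None = None,
    n_clusters: int = 60,
    positions: pd.Series | None = None,
) -> pd.Series:
    """Homeodomain-code clustering on near-binary homeobox expression.

    ``nb_expr`` is genes × cells (homeobox panel only, near-binary values).
    ``hox_mask`` marks cells to exclude (True = Hox-negative).  When
    ``positions`` (inferred AP position per cell) is given, cluster ids are
    relabeled 1..n in order of mean position, anterior first.
    """
    if nb_expr.shape[0] == 0:
        raise ValueError("empty homeobox panel")
    cells = nb_expr.columns
    if hox_mask is not None:
        mask = (
            hox_mask.reindex(cells).to_numpy()
            if isinstance(hox_mask, pd.Series)
            else np.asarray(hox_mask)
        )
        cells = cells[~mask.astype(bool)]
    if len(cells) < n_clusters:
        raise ValueError("n_clusters exceeds the number of retained cells")
    values = nb_expr[cells].to_numpy(dtype=float).T  # cells × genes
    labels = pd.Series(_ward_cells(values, n_clusters), index=cells, name="homeo_cluster")
    if positions is not None:
        mean_pos = positions.reindex(cells).groupby(labels).mean().sort_values()
        relabel = {old: new + 1 for new, old in enumerate(mean_pos.index)}
        labels = labels.map(relabel).rename("homeo_cluster")
    return labels


def subtype_score(
    m: CountMatrix,
    dmn_markers: list[str],
    vmn_markers: list[str],
    min_reads: int = 1,
) -> pd.DataFrame:
    """Dorsal/ventral projection scores: Σ −ln(p_marker) over observed markers.

    p_marker is the fraction of all cells with ≥ min_reads reads of the
    marker, so rare markers contribute more.  Markers never observed are
    excluded with a warning (−log p undefined).  The call is the larger
    score; ties (including all-zero) are ambiguous.
    """
    if not dmn_markers or not vmn_markers:
        raise ValueError("marker sets must be non-empty")

    def _score(markers: list[str]) -> np.ndarray:
        total = np.zeros(m.n_cells)
        for g in markers:
            if g not in m.gene_ids:
                warnings.warn(f"marker {g} not in matrix; skipped", stacklevel=3)
                continue
            row = m.counts[m.gene_index([g])[0], :]
            observed = row >= min_reads
            p = observed.mean()
            if p == 0:
                warnings.warn(f"marker {g} never observed; skipped", stacklevel=3)
                continue
            total += np.where(observed, -np.log(p), 0.0)
        return total

    dmn = _score(dmn_markers)
    vmn = _score(vmn_markers)
    call = np.where(dmn > vmn, "dMN", np.where(vmn > dmn, "vMN", "ambiguous"))
    return pd.DataFrame(
        {"dmn_score": dmn, "vmn_score": vmn, "call": call},
        index=pd.Index(m.cell_ids, name="cell"),
    )


def covariate_check(labels: pd.Series, depth: pd.Series | np.ndarray) -> pd.DataFrame:
    """Rank-sum test of sequencing depth, each cluster vs all other cells."""
    if isinstance(depth, pd.Series):
        depth = depth.reindex(labels.index).to_numpy()
    else:
        depth = np.asarray(depth, dtype=float)
    uniq = np.unique(labels.to_numpy())
    if uniq.size < 2:
        raise ValueError("need ≥ 2 clusters")
    rows = []
    for k in uniq:
        inside = depth[labels.to_numpy() == k]
        outside = depth[labels.to_numpy() != k]
        if np.ptp(depth) == 0:
            p = 1.0  # rank-sum degenerate when all depths tie
        else:
            p = float(mannwhitneyu(inside, outside, alternative="two-sided").pvalue)
        rows.append({"cluster": k, "n": inside.size, "p": p})
    out = pd.DataFrame(rows).set_index("cluster")
    out.attrs["n_below_0.05"] = int((out["p"] < 0.05).sum())
    return out
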