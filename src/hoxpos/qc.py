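"""Cell and gene quality filters and Hox-positivity bookkeeping.

Filters follow the study's QC rule set: a cell is kept when it has at least
``min_reads_per_gene`` reads for each of at least ``min_genes`` genes
(defaults 10 and 500); a gene is kept when at least ``min_cells`` cells have
``min_reads`` reads of it (defaults 5 and 10).  The default stage order is
cells first, then genes; both orders are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    per_cell: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.n_cells_out > self.n_cells_in or self.n_genes_out > self.n_genes_in:
            raise ValueError("output dimensions cannot exceed input dimensions")


def _per_cell_stats(m: CountMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genes_observed": (m.counts >= 1).sum(axis=0),
            "total_reads": m.counts.sum(axis=0),
        },
        index=pd.Index(m.cell_ids, name="cell"),
    )


def filter_cells(
    m: CountMatrix, min_genes: int = 500, min_reads_per_gene: int = 10
) -> tuple[CountMatrix, QCReport]:
    """Keep cells with ≥ min_genes genes at ≥ min_reads_per_gene reads each.

    The report's per-cell statistics are computed on the *input* matrix.
    """
    stats = _per_cell_stats(m)
    qualifying = (m.counts >= min_reads_per_gene).sum(axis=0)
    stats["genes_at_threshold"] = qualifying
    keep = qualifying >= min_genes
    out = m.subset_cells(keep)
    log.info("filter_cells: %d/%d cells retained", out.n_cells, m.n_cells)
    report = QCReport(m.n_cells, out.n_cells, m.n_genes, m.n_genes, stats)
    return out, report


def filter_genes(
    m: CountMatrix, min_cells: int = 5, min_reads: int = 10
) -> CountMatrix:
    """Keep genes with ≥ min_cells cells each having ≥ min_reads reads."""
    keep = (m.counts >= min_reads).sum(axis=1) >= min_cells
    out = m.subset_genes(keep)
    log.info("filter_genes: %d/%d genes retained", out.n_genes, m.n_genes)
    return out


def annotate_hox(
    m: CountMatrix, hox_genes: list[str], min_reads: int = 1
) -> pd.DataFrame:
    """Per-cell count of expressed Hox genes and the exclusion mask.

    "Expressed" means ≥ ``min_reads`` reads (default 1).  Cells expressing no
    Hox gene cannot be position-mapped and are flagged ``hox_negative``.
    Requested genes absent from the matrix are reported and ignored.
    """
    if not hox_genes:
        raise ValueError("hox_genes must be non-empty")
    present = [g for g in hox_genes if g in set(m.gene_ids)]
    missing = sorted(set(hox_genes) - set(present))
    if missing:
        log.warning("Hox genes absent from matrix: %s", missing)
    if not present:
        raise ValueError("none of the requested Hox genes are in the matrix")
    idx = m.gene_index(present)
    n_hox = (m.counts[idx, :] >= min_reads).sum(axis=0)
    return pd.DataFrame(
        {"n_hox_expressed": n_hox, "hox_negative": n_hox == 0},
        index=pd.Index(m.cell_ids, name="cell"),
    )


def mito_fraction(m: CountMatrix, class_label: str = "mitochondrial") -> pd.Series:
    """Per-cell fraction of reads from mitochondrially annotated genes."""
    if m.gene_classes is None:
        raise ValueError("gene_classes annotation required for mito_fraction")
    mito = m.genes_in_class(class_label)
    if not mito:
        raise ValueError(f"no genes annotated {class_label!r}")
    idx = m.gene_index(mito)
    total = m.counts.sum(axis=0).astype(float)
    mito_reads = m.counts[idx, :].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito_reads / total, 0.0)
    return pd.Series(frac, index=pd.Index(m.cell_ids, name="cell"), name="mito_fraction")
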