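"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel either as MatrixMarket coordinate files (1-based
indices, integer field) with ``genes.tsv`` / ``barcodes.tsv`` sidecars, or as
a single dense TSV with genes as rows and a header of cell ids.  Reference
maps, intensity traces and simulation truth are plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, ReferenceMap, SimTruth

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
BARCODES_NAME = "barcodes.tsv"


def _read_class_column(df: pd.DataFrame) -> dict[str, set[str]] | None:
    if df.shape[1] < 2:
        return None
    classes: dict[str, set[str]] = {}
    for gene, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        labels = {c for c in str(cls).split(";") if c and c != "nan"}
        classes[str(gene)] = labels
    return classes


def load_counts(path: str | os.PathLike, format: str | None = None) -> CountMatrix:
    """Load a count matrix from an MTX directory or a dense TSV file.

    ``format`` may be ``"mtx"`` or ``"tsv"``; when omitted it is inferred
    from the path (directory → mtx, file → tsv).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.is_dir() else "tsv"
    if format == "mtx":
        mtx_path = path / MTX_NAME if path.is_dir() else path
        try:
            mat = scipy.io.mmread(mtx_path)
        except Exception as exc:  # scipy raises ValueError on 0-based indices
            raise ValueError(
                f"malformed MatrixMarket file {mtx_path}: {exc}; "
                "coordinate entries must use 1-based indices"
            ) from exc
        mat = scipy.sparse.coo_matrix(mat)
        if mat.nnz == 0 and mat.shape[0] * mat.shape[1] == 0:
            raise ValueError(f"empty matrix in {mtx_path}")
        data = mat.toarray()
        if np.issubdtype(data.dtype, np.floating) and not np.allclose(
            data, np.round(data)
        ):
            raise ValueError("MTX counts must be integers")
        genes_df = pd.read_csv(
            mtx_path.parent / GENES_NAME, sep="\t", header=None, dtype=str
        )
        barcodes = pd.read_csv(
            mtx_path.parent / BARCODES_NAME, sep="\t", header=None, dtype=str
        )
        return CountMatrix(
            data.astype(np.int64),
            list(genes_df.iloc[:, 0]),
            list(barcodes.iloc[:, 0]),
            _read_class_column(genes_df),
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.empty:
            raise ValueError(f"empty matrix file {path}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric entries in {path}")
        return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    raise ValueError(f"unknown format {format!r} (expected 'mtx' or 'tsv')")


def write_counts(m: CountMatrix, path: str | os.PathLike, format: str = "mtx") -> None:
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(m.counts)
        scipy.io.mmwrite(path / MTX_NAME, sparse, field="integer")
        genes = pd.DataFrame({"gene": m.gene_ids})
        if m.gene_classes is not None:
            genes["classes"] = [
                ";".join(sorted(m.gene_classes.get(g, set()))) for g in m.gene_ids
            ]
        genes.to_csv(path / GENES_NAME, sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(
            path / BARCODES_NAME, sep="\t", header=False, index=False
        )
    elif format == "tsv":
        df = pd.DataFrame(m.counts, index=m.gene_ids, columns=m.cell_ids)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_reference(ref: ReferenceMap, path: str | os.PathLike) -> None:
    df = pd.DataFrame(ref.curves, index=ref.gene_ids, columns=ref.grid)
    df.index.name = "gene"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def load_reference(path: str | os.PathLike) -> ReferenceMap:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    grid = df.columns.astype(float).to_numpy()
    return ReferenceMap(grid, df.to_numpy(), list(df.index.astype(str)))


def load_traces(path: str | os.PathLike) -> pd.DataFrame:
    """Long-format intensity traces: columns gene, position, intensity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"gene", "position", "intensity"}
    if not expected.issubset(df.columns):
        raise ValueError(f"trace file must have columns {sorted(expected)}")
    return df


def write_truth(truth: SimTruth, m: CountMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if truth.positions is not None or truth.cluster_labels is not None:
        cells = pd.DataFrame(index=pd.Index(m.cell_ids, name="cell"))
        if truth.positions is not None:
            cells["position"] = truth.positions
        if truth.cluster_labels is not None:
            cells["cluster"] = truth.cluster_labels
        cells.to_csv(path / "truth_cells.tsv", sep="\t")
    if truth.spatial_gene_flags:
        genes = pd.DataFrame(
            {
                "gene": list(truth.spatial_gene_flags),
                "is_spatial": [bool(v) for v in truth.spatial_gene_flags.values()],
            }
        )
        genes.to_csv(path / "truth_genes.tsv", sep="\t", index=False)
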