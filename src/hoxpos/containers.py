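"""Core data containers: the raw count matrix and the AP reference map.

The pipeline keeps counts in genes × cells orientation (genes are rows, as in
the raw count tables) and represents the anterior–posterior (AP) axis as a
fraction in [0, 1].  Converters to the two conventional scales used for the
ventral nerve cord (0–2000 length units and 0–100 %) are provided on
:class:`ReferenceMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


def _as_id_list(ids: Iterable) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        raise ValueError("duplicate identifiers")
    return out


@dataclass
class CountMatrix:
    """Raw integer read counts, genes × cells.

    Parameters
    ----------
    counts
        Nonnegative integer matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    gene_classes
        Optional map ``gene_id -> set of class labels`` (e.g. ``homeobox``,
        ``Ig-domain``, ``Hox``, ``mitochondrial``).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    gene_classes: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes × cells)")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        elif not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.gene_ids = _as_id_list(self.gene_ids)
        self.cell_ids = _as_id_list(self.cell_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def genes_in_class(self, label: str) -> list[str]:
        """Gene ids carrying a given class label (empty if unannotated)."""
        if self.gene_classes is None:
            return []
        return [g for g in self.gene_ids if label in self.gene_classes.get(g, set())]

    def subset_genes(self, keep: np.ndarray | Sequence[str]) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif len(keep) and isinstance(keep[0], str):
            idx = self.gene_index(keep)  # type: ignore[arg-type]
        else:
            idx = np.asarray(keep, dtype=int)
        genes = [self.gene_ids[i] for i in idx]
        classes = None
        if self.gene_classes is not None:
            classes = {g: set(self.gene_classes.get(g, set())) for g in genes}
        return CountMatrix(self.counts[idx, :], genes, list(self.cell_ids), classes)

    def subset_cells(self, keep: np.ndarray | Sequence[str]) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif len(keep) and isinstance(keep[0], str):
            lookup = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([lookup[c] for c in keep], dtype=int)
        else:
            idx = np.asarray(keep, dtype=int)
        cells = [self.cell_ids[i] for i in idx]
        classes = None
        if self.gene_classes is not None:
            classes = {g: set(s) for g, s in self.gene_classes.items()}
        return CountMatrix(self.counts[:, idx], list(self.gene_ids), cells, classes)


@dataclass
class ReferenceMap:
    """Per-gene expected-intensity curves Y_g(x) on a shared AP grid.

    ``grid`` holds axis positions as fractions in [0, 1]; ``curves`` is a
    ``(n_genes, grid_size)`` array with values in [0, 1].  ``Y_g(x) = 0``
    marks territory where gene ``g`` is not expressed — the Poisson mapping
    model treats those positions with the background rate λ.
    """

    grid: np.ndarray
    curves: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        self.gene_ids = _as_id_list(self.gene_ids)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.curves.shape != (len(self.gene_ids), self.grid.size):
            raise ValueError("curves shape inconsistent with genes × grid")
        if (self.curves < 0).any() or (self.curves > 1 + 1e-12).any():
            raise ValueError("curves must lie in [0, 1]")
        self.curves = np.clip(self.curves, 0.0, 1.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def grid_size(self) -> int:
        return self.grid.size

    @property
    def support(self) -> np.ndarray:
        """Boolean (genes × grid): where Y_g(x) > 0."""
        return self.curves > 0

    def grid_in_units(self, total_length: float = 2000.0) -> np.ndarray:
        """Grid on the 0–2000 (or other) nerve-cord length scale."""
        return self.grid * total_length

    def grid_in_percent(self) -> np.ndarray:
        return self.grid * 100.0

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Linear interpolation of every curve at arbitrary axis fractions."""
        positions = np.asarray(positions, dtype=float)
        out = np.empty((self.n_genes, positions.size))
        for i in range(self.n_genes):
            out[i] = np.interp(positions, self.grid, self.curves[i])
        return out

    def resample(self, new_grid_size: int) -> "ReferenceMap":
        if new_grid_size < 2:
            raise ValueError("new_grid_size must be ≥ 2")
        new_grid = np.linspace(self.grid[0], self.grid[-1], new_grid_size)
        new_curves = np.clip(self.interpolate(new_grid), 0.0, 1.0)
        return ReferenceMap(new_grid, new_curves, list(self.gene_ids))


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generators."""

    positions: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    spatial_gene_flags: dict[str, bool] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if ((self.positions < 0) | (self.positions > 1)).any():
                raise ValueError("positions must lie in [0, 1]")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
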