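"""Build AP reference curves Y_g(x) from immunofluorescence intensity traces.

Raw traces (position, intensity) per Hox protein are normalized the way the
nerve-cord measurements are treated: positions rescaled to a common [0, 1]
axis, unspecific background removed by a per-gene intensity quantile
threshold, intensities min–max normalized so each gene attains 1, then
resampled onto a shared grid, with optional exponential-kernel smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ReferenceMap

log = logging.getLogger(__name__)


@dataclass
class IntensityTrace:
    gene: str
    position: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.size != self.intensity.size:
            raise ValueError("position and intensity must have equal length")
        if self.position.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isfinite(self.intensity).all() or (self.intensity < 0).any():
            raise ValueError("intensities must be finite and nonnegative")


def _normalize_trace(
    trace: IntensityTrace,
    grid: np.ndarray,
    background_quantile: float,
    allow_flat: bool,
) -> np.ndarray:
    pos = trace.position
    pos01 = (pos - pos[0]) / (pos[-1] - pos[0])
    v = trace.intensity.astype(float).copy()
    thr = np.quantile(v, background_quantile)
    v[v < thr] = 0.0
    vmax, vmin = v.max(), v.min()
    if vmax == vmin:
        if allow_flat and vmax > 0:
            y = np.ones_like(v)
        else:
            raise ValueError(
                f"trace for {trace.gene} has no dynamic range after background removal"
            )
    else:
        y = (v - vmin) / (vmax - vmin)
    return np.interp(grid, pos01, y)


def exponential_smooth(
    values: np.ndarray, positions: np.ndarray, grid: np.ndarray, decay: float
) -> np.ndarray:
    """Floating mean with absolute exponential weights exp(−decay·|x−x0|)."""
    if decay <= 0:
        raise ValueError("decay must be positive")
    w = np.exp(-decay * np.abs(grid[:, None] - positions[None, :]))
    return (w @ values) / w.sum(axis=1)


def build_reference(
    traces: list[IntensityTrace],
    grid_size: int = 201,
    background_quantile: float = 0.1,
    smooth_decay: float | None = None,
) -> ReferenceMap:
    """Assemble a ReferenceMap from per-gene intensity traces.

    Replicate traces of the same gene are averaged after normalization and
    the average rescaled to attain 1.  ``smooth_decay`` enables
    exponential-kernel smoothing of the resampled curves (decay per unit
    axis); the default is no smoothing.
    """
    if not traces:
        raise ValueError("at least one trace is required")
    if grid_size < 2:
        raise ValueError("grid_size must be ≥ 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    by_gene: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for t in traces:
        if t.gene not in by_gene:
            by_gene[t.gene] = []
            order.append(t.gene)
        by_gene[t.gene].append(
            _normalize_trace(t, grid, background_quantile, allow_flat=False)
        )
    curves = []
    for gene in order:
        reps = by_gene[gene]
        y = np.mean(reps, axis=0)
        if len(reps) > 1:
            log.info("build_reference: averaged %d replicates for %s", len(reps), gene)
        if smooth_decay is not None:
            y = exponential_smooth(y, grid, grid, smooth_decay)
        if y.max() <= 0:
            raise ValueError(f"curve for {gene} is identically zero")
        curves.append(np.clip(y / y.max(), 0.0, 1.0))
    log.info(
        "build_reference: grid=%d, background_quantile=%.3g (threshold not "
        "specified upstream; default is a per-gene intensity quantile), "
        "smooth_decay=%s",
        grid_size,
        background_quantile,
        smooth_decay,
    )
    return ReferenceMap(grid, np.vstack(curves), order)


def resample_reference(ref: ReferenceMap, new_grid_size: int) -> ReferenceMap:
    """Linear-interpolation resampling onto a finer or coarser grid."""
    return ref.resample(new_grid_size)
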