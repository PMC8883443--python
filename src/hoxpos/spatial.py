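"""Spatially-variable-gene selection, profile smoothing and pattern modules.

Per gene, a cubic B-spline model of expression on inferred AP position
(df basis columns plus intercept) is compared with an intercept-only null by
the Bayesian information criterion under a Gaussian likelihood; the gene is
called spatial when the spline model's BIC is lower.  Selected profiles are
smoothed by a floating mean with an absolute exponential kernel (decay rate
10 per unit axis, i.e. a half-width of ≈ 0.07 axis fraction) and grouped by
ward/Euclidean hierarchical clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline

from .reference import exponential_smooth

DEFAULT_DECAY = 10.0


def bspline_design(x: np.ndarray, df: int = 3, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` columns (no intercept).

    With df = degree there are no internal knots and the basis reduces to
    the Bernstein polynomials; extra df adds internal knots at quantiles of
    ``x``.  The leading basis column is dropped so the matrix is full rank
    next to an explicit intercept.
    """
    x = np.asarray(x, dtype=float)
    if df < degree:
        raise ValueError("df must be ≥ spline degree")
    lo, hi = x.min() - 1e-9, x.max() + 1e-9
    n_inner = df - degree
    if n_inner > 0:
        inner = np.quantile(x, np.linspace(0, 1, n_inner + 2)[1:-1])
    else:
        inner = np.array([])
    t = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    design = BSpline.design_matrix(x, t, degree).toarray()
    return design[:, 1:]


def _gaussian_bic(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


def select_spatial_genes(
    scaled_expr: pd.DataFrame, positions: np.ndarray, df: int = 3
) -> pd.DataFrame:
    """BIC comparison of spline-on-position vs intercept-only per gene.

    ``scaled_expr`` is genes × cells, aligned with ``positions`` (axis
    fractions of the same cells).  Returns bic_null, bic_spline, delta_bic
    (positive ⇒ spatial) and is_spatial per gene.
    """
    positions = np.asarray(positions, dtype=float)
    if scaled_expr.shape[1] != positions.size:
        raise ValueError("positions must align with the expression columns")
    if positions.size < 10:
        raise ValueError("need ≥ 10 mapped cells")
    if ((positions < 0) | (positions > 1)).any():
        raise ValueError("positions must be axis fractions in [0, 1]")
    n = positions.size
    intercept = np.ones((n, 1))
    X_spline = np.hstack([intercept, bspline_design(positions, df=df)])
    if n <= X_spline.shape[1]:
        raise ValueError("fewer cells than spline parameters")
    rows = []
    values = scaled_expr.to_numpy(dtype=float)
    for gene, y in zip(scaled_expr.index, values):
        bic_null = _gaussian_bic(y, intercept)
        bic_spline = _gaussian_bic(y, X_spline)
        delta = bic_null - bic_spline
        rows.append((gene, bic_null, bic_spline, delta, delta > 0))
    return pd.DataFrame(
        rows, columns=["gene", "bic_null", "bic_spline", "delta_bic", "is_spatial"]
    ).set_index("gene")


def smooth_profile(
    expr: np.ndarray,
    positions: np.ndarray,
    decay: float = DEFAULT_DECAY,
    grid: np.ndarray | None = None,
) -> pd.Series:
    """Exponential-kernel floating mean of one gene's expression over the axis.

    At each grid point x0 the value is the weighted mean of ``expr`` with
    weights exp(−decay·|x_c − x0|), renormalized to sum to 1.
    """
    expr = np.asarray(expr, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if expr.size != positions.size:
        raise ValueError("expr and positions must align")
    if expr.size < 1:
        raise ValueError("need at least one cell")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    values = exponential_smooth(expr, positions, np.asarray(grid, dtype=float), decay)
    return pd.Series(values, index=np.asarray(grid, dtype=float))


def smooth_profiles(
    scaled_expr: pd.DataFrame,
    positions: np.ndarray,
    decay: float = DEFAULT_DECAY,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Smoothed profiles for every gene in a genes × cells matrix."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    rows = {
        gene: smooth_profile(row, positions, decay, grid).to_numpy()
        for gene, row in zip(scaled_expr.index, scaled_expr.to_numpy(dtype=float))
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=np.asarray(grid))


def cluster_patterns(profiles: pd.DataFrame, n_groups: int = 10) -> pd.Series:
    """Group smoothed profiles into pattern modules (ward/Euclidean).

    Each profile is standardized before clustering so modules reflect shape,
    not amplitude.  Returns integer labels 1..n_groups per gene.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be ≥ 2")
    if profiles.shape[0] < n_groups:
        raise ValueError("need at least n_groups genes")
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / sd, 0.0)
    labels = fcluster(linkage(z, method="ward"), t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=profiles.index, name="pattern_cluster")
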