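"""Maximum-likelihood AP position inference under the Poisson observation model.

For a cell with Hox read counts D_g and reference curves Y_g(x),

    p(D_g | x) = Pois(D_g | r_g · Y_g(x))   if Y_g(x) > 0
               = Pois(D_g | λ)              if Y_g(x) = 0

and the position estimate is the grid argmax of the summed log-likelihood.
λ is the background read rate in non-expressing territory (default 0.1) and
r_g the expected read count at full reference intensity, estimated as the
gene's mean expression over expressing cells.  All computation is in log
space; the product form of the likelihood under- and overflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy
from scipy.stats import qmc

from .containers import CountMatrix, ReferenceMap

DEFAULT_LAMBDA = 0.1


@dataclass
class MappingParams:
    """λ and per-gene r for the Poisson observation model."""

    r: np.ndarray
    lambda_bg: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if (self.r <= 0).any():
            raise ValueError("all r_g must be positive")
        if self.lambda_bg < 0:
            raise ValueError("lambda_bg must be nonnegative")


@dataclass
class PositionEstimate:
    cell: str
    x_hat: float
    loglik_profile: np.ndarray = field(repr=False)
    n_ties: int = 1
    mapped: bool = True
    reason: str | None = None


def estimate_rg(m: CountMatrix, genes: list[str]) -> pd.Series:
    """r_g = total counts of g divided by the number of expressing cells."""
    idx = m.gene_index(genes)
    counts = m.counts[idx, :]
    expressing = (counts > 0).sum(axis=1)
    if (expressing == 0).any():
        dead = [genes[i] for i in np.flatnonzero(expressing == 0)]
        raise ValueError(f"genes with no expressing cells: {dead}")
    return pd.Series(
        counts.sum(axis=1) / expressing, index=pd.Index(genes, name="gene"), name="r"
    )


def expected_counts(ref: ReferenceMap, params: MappingParams) -> np.ndarray:
    """Model mean matrix μ (genes × grid): r_g·Y_g(x) on support, λ elsewhere."""
    if params.r.shape != (ref.n_genes,):
        raise ValueError("r must have one entry per reference gene")
    return np.where(ref.curves > 0, params.r[:, None] * ref.curves, params.lambda_bg)


def cell_log_likelihood(
    d: np.ndarray, ref: ReferenceMap, params: MappingParams
) -> np.ndarray:
    """Log-likelihood profile over the grid for one cell's counts ``d``.

    With λ = 0, a positive count at a zero-support position yields −∞ (never
    NaN); the profile is finite everywhere when λ > 0.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (ref.n_genes,):
        raise ValueError("d must have one count per reference gene")
    mu = expected_counts(ref, params)
    with np.errstate(divide="ignore"):
        ll = xlogy(d[:, None], mu) - mu - gammaln(d + 1.0)[:, None]
    return ll.sum(axis=0)


def _tie_argmax(profile: np.ndarray) -> tuple[int, int]:
    """Index of the profile maximum; ties broken by the median tied index."""
    best = profile.max()
    tol = 1e-9 * max(1.0, abs(best))
    ties = np.flatnonzero(profile >= best - tol)
    return int(ties[(len(ties) - 1) // 2]), int(len(ties))


def map_position(
    d: np.ndarray,
    ref: ReferenceMap,
    params: MappingParams,
    cell: str = "cell",
    require_hox: bool = True,
) -> PositionEstimate:
    """MLE position for one cell; unmapped if it expresses no mapped gene."""
    d = np.asarray(d, dtype=float)
    if require_hox and d.sum() < 1:
        return PositionEstimate(
            cell=cell,
            x_hat=float("nan"),
            loglik_profile=np.full(ref.grid_size, np.nan),
            n_ties=0,
            mapped=False,
            reason="no reads in any mapped gene",
        )
    profile = cell_log_likelihood(d, ref, params)
    idx, n_ties = _tie_argmax(profile)
    return PositionEstimate(
        cell=cell,
        x_hat=float(ref.grid[idx]),
        loglik_profile=profile,
        n_ties=n_ties,
        mapped=True,
    )


def map_cells(
    m: CountMatrix,
    ref: ReferenceMap,
    params: MappingParams,
    require_hox: bool = True,
) -> pd.DataFrame:
    """Vectorized MLE mapping of every cell.

    Returns a per-cell table (x_hat, x_hat_units, n_ties, mapped,
    max_loglik); gene order in the matrix is irrelevant — counts are aligned
    to the reference genes by id.
    """
    idx = m.gene_index(ref.gene_ids)
    D = m.counts[idx, :].astype(float)  # genes × cells
    mu = expected_counts(ref, params)
    if params.lambda_bg > 0:
        log_mu = np.log(mu)
        L = D.T @ log_mu - mu.sum(axis=0)[None, :] - gammaln(D + 1.0).sum(axis=0)[:, None]
    else:
        with np.errstate(divide="ignore"):
            L = np.stack(
                [cell_log_likelihood(D[:, c], ref, params) for c in range(D.shape[1])]
            )
    rows = []
    for c, cell in enumerate(m.cell_ids):
        if require_hox and D[:, c].sum() < 1:
            rows.append((cell, np.nan, np.nan, 0, False, np.nan))
            continue
        i, n_ties = _tie_argmax(L[c])
        rows.append((cell, ref.grid[i], ref.grid[i] * 2000.0, n_ties, True, L[c, i]))
    return pd.DataFrame(
        rows,
        columns=["cell", "x_hat", "x_hat_units0_2000", "n_ties", "mapped", "max_loglik"],
    ).set_index("cell")


def robustness_lhs(
    m: CountMatrix,
    ref: ReferenceMap,
    n_draws: int = 20,
    lambda_range: tuple[float, float] = (0.01, 1.0),
    r_scale_range: tuple[float, float] = (0.2, 5.0),
    seed: int = 0,
    base_r: np.ndarray | pd.Series | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Latin-hypercube scan of (λ, global r multiplier) parameter space.

    Re-estimates every cell's position for each drawn parameter set and
    returns the matrix of pairwise Spearman correlations between the draws'
    position vectors (mapped cells only) plus the design table.  Parameters
    are sampled log-uniformly within their ranges.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be ≥ 2")
    for lo, hi in (lambda_range, r_scale_range):
        if not (0 < lo <= hi):
            raise ValueError("ranges must be positive with lo ≤ hi")
    if base_r is None:
        base_r = estimate_rg(m, ref.gene_ids).to_numpy()
    else:
        base_r = np.asarray(base_r, dtype=float)
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    u = sampler.random(n_draws)

    def _logscale(ui: np.ndarray, lo: float, hi: float) -> np.ndarray:
        return lo * (hi / lo) ** ui if hi > lo else np.full_like(ui, lo)

    lam = _logscale(u[:, 0], *lambda_range)
    mult = _logscale(u[:, 1], *r_scale_range)
    positions = []
    for i in range(n_draws):
        params = MappingParams(r=base_r * mult[i], lambda_bg=lam[i])
        res = map_cells(m, ref, params)
        positions.append(res.loc[res["mapped"], "x_hat"].to_numpy())
    pos = np.vstack(positions)
    corr = np.ones((n_draws, n_draws))
    for i in range(n_draws):
        for j in range(i + 1, n_draws):
            if np.array_equal(pos[i], pos[j]):
                rho = 1.0
            else:
                rho = stats.spearmanr(pos[i], pos[j]).statistic
            corr[i, j] = corr[j, i] = rho
    design = pd.DataFrame({"lambda_bg": lam, "r_multiplier": mult})
    return corr, design
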