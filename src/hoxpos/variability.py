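"""Highly-variable-gene detection via the CV²-vs-mean technical-noise model.

The technical trend CV² = a1/μ + a0 is fitted across genes by a Gamma-family
GLM with identity link (the canonical published estimator for this model),
and each gene's observed variance is compared to the fitted technical
expectation with a chi-square test on n−1 degrees of freedom, followed by
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

log = logging.getLogger(__name__)


def size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over genes detected
    in every cell; when no such gene exists the total-count fallback is used.
    """
    counts = m.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    all_positive = (counts > 0).all(axis=1)
    sf = None
    if all_positive.any():
        sub = counts[all_positive, :]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        sf = np.median(sub / ref[:, None], axis=0)
        if (sf <= 0).any() or not np.isfinite(sf).all():
            sf = None
    if sf is None:
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            totals = np.where(totals > 0, totals, totals[totals > 0].min())
        sf = totals / totals.mean()
        log.info("size_factors: total-count fallback used")
    return sf / np.exp(np.mean(np.log(sf)))


@dataclass
class NoiseFit:
    """Fitted technical-noise parameters for the CV²-vs-mean trend."""

    a0: float
    a1: float
    size_factors: np.ndarray
    fit_support: list[str]
    means: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]
    cv2: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]

    def technical_cv2(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a1 / mu + self.a0

    def technical_variance(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return self.a1 * mu + self.a0 * mu**2


def _normalized(m: CountMatrix, sf: np.ndarray) -> np.ndarray:
    return m.counts / sf[None, :]


def fit_technical_noise(
    m: CountMatrix, sf: np.ndarray, min_mean_quantile: float = 0.3
) -> NoiseFit:
    """Fit CV² = a1/μ + a0 on genes above a mean-expression quantile."""
    norm = _normalized(m, sf)
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    expressed = mu > 0
    if expressed.sum() < 10:
        raise ValueError("need ≥ 10 expressed genes to fit the noise model")
    threshold = np.quantile(mu[expressed], min_mean_quantile)
    use = expressed & (mu >= threshold) & np.isfinite(cv2)
    if use.sum() < 10:
        raise ValueError("need ≥ 10 genes above the mean quantile for the fit")
    X = sm.add_constant(1.0 / mu[use])
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # identity-link Gamma domain notice
            fit = sm.GLM(
                cv2[use], X, family=sm.families.Gamma(link=sm.families.links.Identity())
            ).fit(start_params=np.array([0.1, 1.0]))
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    except Exception:  # degenerate GLM; ordinary least squares fallback
        beta, *_ = np.linalg.lstsq(X, cv2[use], rcond=None)
        a0, a1 = float(beta[0]), float(beta[1])
        log.warning("fit_technical_noise: Gamma GLM failed, OLS fallback used")
    if not (np.isfinite(a0) and np.isfinite(a1)):
        raise ValueError("degenerate technical-noise fit (non-finite coefficients)")
    genes = pd.Index(m.gene_ids)
    return NoiseFit(
        a0=a0,
        a1=a1,
        size_factors=sf,
        fit_support=[m.gene_ids[i] for i in np.flatnonzero(use)],
        means=pd.Series(mu, index=genes, name="mean"),
        cv2=pd.Series(cv2, index=genes, name="cv2"),
    )


def test_variable_genes(
    m: CountMatrix, fit: NoiseFit, fdr: float = 0.1
) -> pd.DataFrame:
    """Chi-square test of each gene's variance against the technical trend.

    Returns a per-gene table with columns ``mean``, ``cv2``, ``p``, ``p_adj``
    and ``is_variable`` (BH-adjusted p ≤ fdr).
    """
    norm = _normalized(m, fit.size_factors)
    n = m.n_cells
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    var_tech = fit.technical_variance(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var_tech > 0, (n - 1) * var / var_tech, 0.0)
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    p = stats.chi2.sf(stat, df=n - 1)
    p = np.where(mu > 0, p, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean": mu,
            "cv2": cv2,
            "p": p,
            "p_adj": p_adj,
            "is_variable": p_adj <= fdr,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )


def class_enrichment_hypergeometric(
    variable: set[str], class_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene class among HVGs."""
    if not universe:
        raise ValueError("empty universe")
    variable = set(variable) & set(universe)
    M, n = len(universe), len(variable)
    rows = []
    for name, genes in class_sets.items():
        in_class = set(genes) & set(universe)
        k = len(variable & in_class)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_class), n))
        rows.append({"class": name, "class_size": len(in_class), "overlap": k, "p": p})
    return pd.DataFrame(rows).set_index("class")


def scale_expression(m: CountMatrix, fit: NoiseFit) -> pd.DataFrame:
    """Normalize, log1p-transform and standardize to fitted total variance.

    Recipe (logged here once): counts are divided by the fit's size factors,
    log1p-transformed, centered per gene, and divided by the square root of
    the fitted total variance on the log scale — the observed log-scale
    variance or, if smaller, the technical variance propagated to the log
    scale by the delta method (var_tech / (1+μ)²).  Constant genes map to 0.
    """
    norm = _normalized(m, fit.size_factors)
    x = np.log1p(norm)
    mu = norm.mean(axis=1)
    var_obs_log = x.var(axis=1, ddof=1)
    var_tech_log = fit.technical_variance(mu) / (1.0 + mu) ** 2
    total = np.maximum(var_obs_log, var_tech_log)
    centered = x - x.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(total[:, None] > 0, centered / np.sqrt(total)[:, None], 0.0)
    return pd.DataFrame(scaled, index=pd.Index(m.gene_ids, name="gene"), columns=m.cell_ids)
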