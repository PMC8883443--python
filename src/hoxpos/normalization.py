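"""Near-binarizing gene-wise log_k normalization.

For one gene, let s_i = x_i / Σ_j x_j be cell i's share of the gene's total
size-factor-normalized counts.  The transform

    N_i = ln(1 + k·s_i) / ln(k)

maps zeros to exactly 0 and tends to an on/off indicator as k → ∞, while for
highly expressed genes (large shares) quantitative differences survive.  The
default gain is k = 10⁶, at which lowly expressed genes are essentially
binarized.  An alternative, non-binarizing reading ln(1 + s_i)/ln(k) is kept
behind ``variant="plain"`` for comparison; it tends to 0 for all inputs as
k grows and is not used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

DEFAULT_K = 1e6


@dataclass(frozen=True)
class NearBinaryParams:
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.k > 1:
            raise ValueError("k must be > 1")


def near_binary_transform(
    x: np.ndarray, params: NearBinaryParams | float = DEFAULT_K, variant: str = "scaled"
) -> np.ndarray:
    """Apply the log_k share transform to one gene's per-cell values.

    All-zero genes pass through as zeros.  Output lies in [0, log_k(1+k)].
    """
    k = params.k if isinstance(params, NearBinaryParams) else float(params)
    if not k > 1:
        raise ValueError("k must be > 1")
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("input must be nonnegative")
    total = x.sum()
    if total == 0:
        return np.zeros_like(x)
    s = x / total
    if variant == "scaled":
        return np.log1p(k * s) / np.log(k)
    if variant == "plain":
        return np.log1p(s) / np.log(k)
    raise ValueError(f"unknown variant {variant!r}")


def near_binary_matrix(
    m: CountMatrix | pd.DataFrame | np.ndarray,
    size_factors: np.ndarray | None = None,
    params: NearBinaryParams | float = DEFAULT_K,
    variant: str = "scaled",
) -> pd.DataFrame:
    """Gene-wise transform of a whole genes × cells matrix.

    When ``size_factors`` is given, counts are divided by them first (the
    transform itself is invariant to any further global scaling of a gene).
    """
    if isinstance(m, CountMatrix):
        values = m.counts.astype(float)
        index, columns = pd.Index(m.gene_ids, name="gene"), m.cell_ids
    elif isinstance(m, pd.DataFrame):
        values = m.to_numpy(dtype=float)
        index, columns = m.index, m.columns
    else:
        values = np.asarray(m, dtype=float)
        index = pd.RangeIndex(values.shape[0])
        columns = pd.RangeIndex(values.shape[1])
    if size_factors is not None:
        values = values / np.asarray(size_factors)[None, :]
    out = np.vstack(
        [near_binary_transform(row, params, variant) for row in values]
    )
    return pd.DataFrame(out, index=index, columns=columns)
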