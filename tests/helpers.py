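"""Shared helpers for the test suite (independent oracles and fixtures)."""

import itertools
from math import comb

import numpy as np

from hoxpos import CountMatrix


def random_count_matrix(rng, n_genes=12, n_cells=8, max_count=30):
    counts = rng.integers(0, max_count, size=(n_genes, n_cells))
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
    )


def enumerate_hypergeom_upper_tail(universe, set_a, set_b):
    """P(overlap ≥ observed) by exhaustive enumeration of all |B|-subsets."""
    universe = sorted(universe)
    a = set(set_a)
    k_obs = len(a & set(set_b))
    total = hits = 0
    for draw in itertools.combinations(universe, len(set_b)):
        total += 1
        if len(a & set(draw)) >= k_obs:
            hits += 1
    return hits / total


def enumerate_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric outcomes at most as likely."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
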