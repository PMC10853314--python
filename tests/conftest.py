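"""Shared helpers for the statistical tests.

Monte-Carlo assertions use 3-standard-error bands and chi-square /
Kolmogorov-Smirnov tests at alpha = 0.001, each with a fixed seed, so a
clean implementation fails any single check with probability well below
one in a few hundred.
"""

import numpy as np
import pytest
from scipy import stats

import yuleimm as ym
from yuleimm.params import CountsOfCounts

ALPHA = 1e-3


def esf_table(n: int, theta: float) -> dict[tuple, float]:
    """Map sorted-descending family-size tuples (zero-padded to n) -> ESF prob."""
    out = {}
    for cc in ym.iter_counts_of_counts(n):
        sizes = cc.sizes() + [0] * (n - cc.num_families)
        out[tuple(sizes[:n])] = ym.esf_pmf(cc, theta)
    return out


def partition_frequencies(sizes_matrix: np.ndarray) -> dict[tuple, int]:
    """Count occurrences of each sorted-size row in a (reps, n) matrix."""
    uniq, counts = np.unique(sizes_matrix, axis=0, return_counts=True)
    return {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, counts)}


def chisquare_vs_esf(sizes_matrix: np.ndarray, n: int, theta: float) -> float:
    """p-value of a chi-square GOF of empirical partitions against the ESF."""
    table = esf_table(n, theta)
    freqs = partition_frequencies(sizes_matrix)
    assert set(freqs) <= set(table), "simulated a partition outside the support"
    keys = sorted(table)
    reps = sizes_matrix.shape[0]
    observed = np.array([freqs.get(k, 0) for k in keys], dtype=float)
    expected = np.array([table[k] * reps for k in keys])
    res = stats.chisquare(observed, expected * observed.sum() / expected.sum())
    return float(res.pvalue)


def assert_within_se(empirical: float, exact: float, se: float, n_se: float = 3.0):
    assert abs(empirical - exact) <= n_se * se, (
        f"empirical {empirical:.5g} vs exact {exact:.5g} "
        f"is {abs(empirical - exact) / se:.2f} SE away")
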