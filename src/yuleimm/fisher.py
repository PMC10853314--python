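"""Fisher's multi-sampling problem for the BI process.

Successive samples of sizes ``n_1, ..., n_p`` are matched to time windows
by requiring the expected cumulative number of individuals at the window
boundaries to equal the cumulative sample sizes. The per-window observable
family counts are then Poisson with explicit means and covariances, their
expected sample variance has a closed form, and for equal sample sizes it
converges to Fisher's classical limit ``theta * log 2`` at rate O(1/n).
Unit birth rate throughout (the boundary-matching construction fixes the
clock).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import analytic
from .params import BIParams, TimePartition

__all__ = [
    "SampleSizePlan",
    "fisher_times",
    "tilde_moments",
    "tilde_esv",
    "equal_n_esv",
    "asymptotic_esv",
    "prop1_limits",
]


@dataclass(frozen=True)
class SampleSizePlan:
    """Sizes of p successive samples.

    Attributes
    ----------
    sizes : tuple of int
        ``n_1, ..., n_p``, all >= 1.
    """

    sizes: tuple[int, ...]

    def __init__(self, sizes: Iterable[int]):
        s = tuple(int(x) for x in sizes)
        if len(s) < 1 or any(x < 1 for x in s):
            raise ValueError("need at least one sample, all sizes >= 1")
        object.__setattr__(self, "sizes", s)

    @property
    def p(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return int(sum(self.sizes))

    @property
    def cum(self) -> np.ndarray:
        """Cumulative sizes ``l_0 = 0, l_1, ..., l_p``."""
        return np.concatenate([[0], np.cumsum(self.sizes)])

    @property
    def proportions(self) -> np.ndarray:
        """``q_i = n_i / n`` for the large-n asymptotics."""
        return np.asarray(self.sizes, dtype=float) / self.n


def fisher_times(plan: SampleSizePlan, theta: float) -> TimePartition:
    """Window boundaries matching expected cumulative sample sizes.

    ``t_i = log((theta + l_i)/theta)`` solves ``E Z(t_i) = l_i``; these are
    simultaneously the moment and maximum-likelihood estimators of the
    sampling times when theta is known and the counts are observed.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    return TimePartition.fisher(plan.sizes, theta)


def tilde_moments(plan: SampleSizePlan, theta: float):
    """Means and covariances of the per-window counts at Fisher times.

    Returns ``(means, cov)`` where ``means[i] = theta*log((theta+n_i)/theta)``
    and ``cov(i, j) = theta*log[(theta+n_i)(theta+n_j) /
    (theta*(theta+n_i+n_j))]`` for i != j (the variance is the Poisson mean).
    These coincide with :func:`yuleimm.analytic.mean_observed` /
    :func:`yuleimm.analytic.cov_observed` evaluated at the Fisher
    boundaries.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    n = np.asarray(plan.sizes, dtype=float)
    means = theta * np.log1p(n / theta)

    def cov(i: int, j: int) -> float:
        if i == j:
            return float(means[i])
        ni, nj = n[i], n[j]
        return float(theta * np.log((theta + ni) * (theta + nj)
                                    / (theta * (theta + ni + nj))))

    return means, cov


def tilde_esv(plan: SampleSizePlan, theta: float) -> float:
    """Exact expected sample variance of the counts at Fisher times.

    ``(1/(p(p-1))) sum_{i<j} { theta log[(theta+n_i+n_j)^2 /
    ((theta+n_i)(theta+n_j))] + theta^2 log^2[(theta+n_i)/(theta+n_j)] }``.

    Identical to :func:`yuleimm.analytic.expected_sample_variance` on the
    Fisher partition (the boundary matching turns the window weights
    ``e^{t_i} - e^{t_{i-1}}`` into ``n_i / theta``).
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    p = plan.p
    if p < 2:
        raise ValueError(f"need at least 2 samples, got p={p}")
    n = np.asarray(plan.sizes, dtype=float)
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            ni, nj = n[i], n[j]
            total += theta * np.log((theta + ni + nj) ** 2
                                    / ((theta + ni) * (theta + nj)))
            total += theta ** 2 * np.log((theta + ni) / (theta + nj)) ** 2
    return total / (p * (p - 1))


def equal_n_esv(n: int, theta: float) -> float:
    """Expected sample variance for equal sample sizes n.

    ``theta * log((2n + theta)/(n + theta))`` — Fisher's quantity;
    increasing in n with limit ``theta * log 2`` and error
    ``|theta * log(1 - theta/(2(n + theta)))| = O(1/n)``.

    ``n = 0`` is accepted as the degenerate limit (value 0).
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return float(theta * np.log((2 * n + theta) / (n + theta)))


def asymptotic_esv(proportions: Iterable[float], theta: float) -> float:
    """Large-n limit of the expected sample variance for ``n_i = q_i n``.

    ``(1/(p(p-1))) sum_{i<j} { theta log[(q_i+q_j)^2/(q_i q_j)] +
    theta^2 log^2(q_i/q_j) }``; for equal proportions this is
    ``theta * log 2``. :func:`tilde_esv` converges to it at rate O(1/n).
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    q = np.asarray(list(proportions), dtype=float)
    p = q.size
    if p < 2:
        raise ValueError(f"need at least 2 samples, got p={p}")
    if np.any(q <= 0) or np.any(q >= 1) or not np.isclose(q.sum(), 1.0, atol=1e-12):
        raise ValueError("proportions must lie in (0, 1) and sum to 1")
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            total += theta * np.log((q[i] + q[j]) ** 2 / (q[i] * q[j]))
            total += theta ** 2 * np.log(q[i] / q[j]) ** 2
    return total / (p * (p - 1))


def prop1_limits(tau: float, p: int, theta: float) -> tuple[float, float]:
    """Large-birth-rate limits of the two Table-style expected sample variances.

    As ``lam -> inf`` with theta, tau, p fixed:

    - equal-length windows: ``E V_p -> theta*tau*(theta*tau + 2)*(p + 1)/(12 p)``;
    - logarithmically equal windows: ``E V_p -> 0``.
    """
    if theta <= 0 or tau <= 0:
        raise ValueError("theta and tau must be > 0")
    if p < 2:
        raise ValueError(f"need at least 2 windows, got p={p}")
    tt = theta * tau
    return tt * (tt + 2.0) * (p + 1) / (12.0 * p), 0.0
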