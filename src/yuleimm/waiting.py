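"""Waiting time until a randomly chosen family's next birth.

Conditional on at least one family arriving in (0, t), pick one of those
families uniformly at random. Its size N_t at time t is log-series
distributed with parameter ``q_t = 1 - e^{-t}`` (a typical founding time
is uniform on (0, t), so the geometric Yule size mixes to the log-series).
Given N_t = n, each of the n members independently waits an Exp(1) time
for its next birth, so the residual waiting time W_t is Exp(n); the
mixture gives an explicit density, distribution function and
polylogarithm moments.

Unit birth rate throughout; for a general rate, time rescales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import zeta

from .params import BIParams
from .simulate import simulate_bi

__all__ = [
    "WaitingLaw",
    "logseries_pmf",
    "waiting_density",
    "waiting_cdf",
    "waiting_moments",
    "WaitingMoments",
    "polylog",
    "sample_waiting_times",
]


@dataclass(frozen=True)
class WaitingLaw:
    """The waiting-time law at observation time t > 0.

    ``q = 1 - e^{-t}`` is the log-series parameter of the size N_t of the
    randomly chosen family; ``-log(1 - q) = t``.
    """

    t: float

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"observation time must be > 0, got {self.t}")

    @property
    def q(self) -> float:
        return float(-np.expm1(-self.t))


def logseries_pmf(j: int | np.ndarray, law: WaitingLaw) -> float | np.ndarray:
    """P(N_t = j) = q^j / (j t): log-series size of the chosen family."""
    j = np.asarray(j)
    if np.any(j < 1):
        raise ValueError("family size must be >= 1")
    out = np.exp(j * np.log(law.q)) / (j * law.t)
    return float(out) if out.ndim == 0 else out


def waiting_density(s: float | np.ndarray, law: WaitingLaw) -> float | np.ndarray:
    """Density of W_t at s > 0.

    ``f_t(s) = (1 - e^{-t}) e^{-s} / (t (1 - e^{-s}(1 - e^{-t})))`` —
    the Exp(n) mixture over the log-series size; integrates to 1.
    As t -> 0+ it tends pointwise to the unit exponential (a lone
    founder).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("the waiting time is supported on s > 0")
    q = law.q
    out = q * np.exp(-s) / (law.t * (1.0 - q * np.exp(-s)))
    return float(out) if out.ndim == 0 else out


def waiting_cdf(u: float | np.ndarray, law: WaitingLaw) -> float | np.ndarray:
    """P(W_t <= u) = (1/t) * log(e^{-u} + e^t - e^{t-u}) for u >= 0.

    Zero at u = 0, tending to 1 as u -> inf, non-decreasing.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be >= 0")
    # e^{-u} + e^t - e^{t-u} = e^t (1 - e^{-u}(1 - e^{-t})) ; log it stably,
    # clipping the last-ulp round-off at u = 0 into the probability range
    out = np.clip((law.t + np.log1p(-law.q * np.exp(-u))) / law.t, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def polylog(n: int, x: float) -> float:
    """Polylogarithm ``Li_n(x) = sum_{k>=1} x^k / k^n`` by direct series.

    Supports ``0 <= x < 1`` for any order ``n >= 1`` and ``x = 1`` for
    ``n >= 2`` (Riemann zeta). The series is summed in blocks until the
    geometric tail bound ``x^{K+1} / ((1-x) (K+1)^n)`` drops below 1e-13.
    """
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    if x < 0 or x > 1:
        raise ValueError(f"argument must lie in [0, 1], got {x}")
    if x == 1.0:
        if n == 1:
            raise ValueError("Li_1(1) diverges")
        return float(zeta(n))
    if x == 0.0:
        return 0.0
    total = 0.0
    k0 = 1
    block = 4096
    while True:
        k = np.arange(k0, k0 + block, dtype=float)
        total += float(np.sum(np.exp(k * np.log(x)) / k ** n))
        k0 += block
        tail = np.exp(k0 * np.log(x)) / ((1.0 - x) * k0 ** n)
        if tail < 1e-13:
            return total


class WaitingMoments(NamedTuple):
    mean: float
    variance_paper: float
    variance_derived: float


def waiting_moments(law: WaitingLaw) -> WaitingMoments:
    """Mean and variance of W_t via polylogarithms.

    ``E W_t = Li_2(q_t)/t``. Two variance candidates are returned:
    ``variance_paper = Li_3(q_t)/t`` (the form sometimes quoted for this
    law) and ``variance_derived = 2 Li_3(q_t)/t - (Li_2(q_t)/t)^2``, which
    follows from ``E[W_t^2 | N_t = n] = 2/n^2`` under the Exp(n)/log-series
    mixture. Numerical quadrature of the density confirms the derived
    form is the actual variance; it is the canonical one.
    """
    q, t = law.q, law.t
    li2 = polylog(2, q)
    li3 = polylog(3, q)
    mean = li2 / t
    return WaitingMoments(mean, li3 / t, 2.0 * li3 / t - mean ** 2)


def sample_waiting_times(theta: float, t: float, reps: int, seed=None) -> np.ndarray:
    """Simulate W_t from event-level BI realizations.

    Each replicate simulates the BI process (unit birth rate) to time t,
    conditions on at least one family having arrived (resampling
    otherwise), picks one family uniformly, and draws the minimum of its
    N_t members' independent Exp(1) residual birth waits — the memoryless
    property makes this the exact residual law.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    params = BIParams(theta=theta, lam=1.0)
    out = np.empty(reps)
    for r in range(reps):
        while True:
            pop = simulate_bi(params, t, rng)
            if pop.num_families > 0:
                break
        fam = pop.families[rng.integers(pop.num_families)]
        n = fam.size_at(t)
        out[r] = rng.exponential() / n
    return out
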