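"""Closed-form distributions and moments for the BI process.

Everything here is exact and deterministic: Yule-family marginals, the
marked-Poisson means for families (un)observable in given windows, the
observable-count means/covariances across disjoint windows, the expected
sample variance of the per-window counts for arbitrary / equal /
logarithmically-equal partitions, and the Ewens Sampling Formula pmf.

All formulas are derived on the unit-birth-rate clock (``lam = 1``); each
operation taking :class:`~yuleimm.params.BIParams` applies the substitution
``t -> lam*t``, ``theta -> theta/lam`` internally.  Expressions of the form
``log(e^x - e^y + k)`` are evaluated through ``logsumexp`` with signs, so
scaled horizons up to ``lam*tau ~ 700`` are safe.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from sympy.utilities.iterables import partitions as _sympy_partitions

from .params import BIParams, CountsOfCounts, Interval, TimePartition

__all__ = [
    "yule_pmf",
    "yule_pgf",
    "phi_integral",
    "family_count_mean",
    "popsize_pmf",
    "popsize_mean",
    "mean_unobservable",
    "mean_unobservable_two",
    "mean_observable",
    "decomposition_means",
    "mean_observed",
    "cov_observed",
    "expected_sample_variance",
    "equal_intervals_esv",
    "log_intervals_esv",
    "correlation_log_equal",
    "esf_pmf",
    "iter_counts_of_counts",
]


# ---------------------------------------------------------------------------
# numerically stable building block
# ---------------------------------------------------------------------------

def _log_comb(exponents, signs) -> float:
    """log of a signed exponential combination sum_i s_i * e^{x_i} (> 0)."""
    val, sign = logsumexp(np.asarray(exponents, dtype=float),
                          b=np.asarray(signs, dtype=float), return_sign=True)
    if sign <= 0:
        raise ValueError("exponential combination is not positive")
    return float(val)


def _log_w1(x: float, y: float) -> float:
    """log(e^x - e^y + 1) for x >= y >= 0."""
    return _log_comb([x, y, 0.0], [1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# Yule-family marginals
# ---------------------------------------------------------------------------

def yule_pmf(j: int, t: float) -> float:
    """P(B(t) = j) for a Yule family grown from one founder for time t.

    The size is geometric: ``e^{-t} (1 - e^{-t})^{j-1}``. Unit birth rate;
    rescale ``t -> lam*t`` for a general rate.
    """
    if j < 1:
        raise ValueError(f"family size must be >= 1, got {j}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if t == 0:
        return 1.0 if j == 1 else 0.0
    return float(np.exp(-t + (j - 1) * np.log(-np.expm1(-t))))


def yule_pgf(t: float, s: float) -> float:
    """Probability generating function ``E s^{B(t)}`` of the Yule family size.

    ``phi(t; s) = e^{-t} s / (1 - (1 - e^{-t}) s)`` for ``0 <= s <= 1``.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"pgf argument must lie in [0, 1], got {s}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    q = -np.expm1(-t)  # 1 - e^{-t}
    return float(np.exp(-t) * s / (1.0 - q * s))


def phi_integral(a: float, b: float, c: float, s: float) -> float:
    """``int_a^b phi(c - u; s) du`` in closed form.

    Equals ``log[(1 - (1 - e^{-(c-b)}) s) / (1 - (1 - e^{-(c-a)}) s)]``
    for ``a <= b <= c`` and ``s`` in ``[0, 1]``.
    """
    if not (a <= b <= c):
        raise ValueError(f"need a <= b <= c, got ({a}, {b}, {c})")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"pgf argument must lie in [0, 1], got {s}")
    num = 1.0 - -np.expm1(-(c - b)) * s
    den = 1.0 - -np.expm1(-(c - a)) * s
    return float(np.log(num) - np.log(den))


def family_count_mean(i: int, t: float, params: BIParams) -> float:
    """``E C_i(t)``, the expected number of families of size i at time t.

    The counts ``C_i(t)`` are independent Poissons with mean
    ``(theta/lam) * (1 - e^{-lam t})^i / i``; as ``t -> inf`` this tends
    to ``theta/(lam i)``.
    """
    if i < 1:
        raise ValueError(f"family size must be >= 1, got {i}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    ts = params.lam * t
    if ts == 0:
        return 0.0
    return float(params.theta_scaled * np.exp(i * np.log(-np.expm1(-ts))) / i)


def popsize_pmf(n: int, t: float, params: BIParams) -> float:
    """P(Z(t) = n): negative-binomial population size at time t.

    ``Z(t) ~ NB(theta/lam, e^{-lam t})`` with
    ``P(Z = n) = C(theta' + n - 1, n) e^{-theta' t'} (1 - e^{-t'})^n``
    on the scaled clock ``t' = lam t``, ``theta' = theta/lam``;
    mean ``theta' * (e^{t'} - 1)``.
    """
    if n < 0:
        raise ValueError(f"population size must be >= 0, got {n}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    th, ts = params.theta_scaled, params.lam * t
    if ts == 0:
        return 1.0 if n == 0 else 0.0
    logp = (gammaln(th + n) - gammaln(n + 1) - gammaln(th)
            - th * ts + n * np.log(-np.expm1(-ts)))
    return float(np.exp(logp))


def popsize_mean(t: float, params: BIParams) -> float:
    """``E Z(t) = (theta/lam) * (e^{lam t} - 1)``."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return float(params.theta_scaled * np.expm1(params.lam * t))


# ---------------------------------------------------------------------------
# marked-Poisson means for (un)observable families
# ---------------------------------------------------------------------------

def _scaled(params: BIParams, *times: float) -> tuple:
    return (params.theta_scaled,) + tuple(params.lam * t for t in times)


def mean_unobservable(J: Interval, I: Interval, params: BIParams) -> float:
    """``E V_J(I)``: families founded in J = (a, b) with no birth in I = (c, d).

    ``theta * log[(e^d - e^c + e^b) / (e^d - e^c + e^a)]`` on the scaled
    clock. Requires ``b <= c``; a degenerate I (``c == d``) is allowed and
    gives ``theta*(b - a)`` — every arrival in J is then trivially
    unobservable in I.
    """
    if J.b > I.a:
        raise ValueError(f"need J.b <= I.a, got J={J}, I={I}")
    th, a, b, c, d = _scaled(params, J.a, J.b, I.a, I.b)
    num = _log_comb([d, c, b], [1, -1, 1])
    den = _log_comb([d, c, a], [1, -1, 1])
    return th * (num - den)


def mean_unobservable_two(a: float, I1: Interval, I2: Interval,
                          params: BIParams) -> float:
    """``E V_{(0,a)}(I1, I2)``: families founded before a with no birth in
    I1 = (a, b) or I2 = (c, d).

    ``theta * log[(e^d - e^c + e^b) / (e^d - e^c + e^b - e^a + 1)]``.
    Requires ``a <= I1.a`` (= a), ``I1.b <= I2.a``. An empty founding window
    (``a == 0``) gives 0.
    """
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    if not (a <= I1.a and I1.b <= I2.a):
        raise ValueError(f"need a <= I1.a and I1.b <= I2.a, got a={a}, I1={I1}, I2={I2}")
    if a == 0:
        return 0.0
    th, a_, b, c, d = _scaled(params, a, I1.b, I2.a, I2.b)
    num = _log_comb([d, c, b], [1, -1, 1])
    den = _log_comb([d, c, b, a_, 0.0], [1, -1, 1, -1, 1])
    return th * (num - den)


def mean_observable(J: Interval, I: Interval, params: BIParams) -> float:
    """``E U_J(I)``: families founded in J = (a, b) with >= 1 birth in I = (c, d).

    ``theta * log[e^b (e^d - e^c + e^a) / (e^a (e^d - e^c + e^b))]``.
    Satisfies the additivity identity
    ``E U_J(I) + E V_J(I) = theta * |J|`` exactly, since every family
    founded in J is either observable in I or not.
    """
    if J.b > I.a:
        raise ValueError(f"need J.b <= I.a, got J={J}, I={I}")
    if I.degenerate:
        return 0.0
    th, a, b, c, d = _scaled(params, J.a, J.b, I.a, I.b)
    num = _log_comb([d, c, a], [1, -1, 1])
    den = _log_comb([d, c, b], [1, -1, 1])
    return th * ((b - a) + num - den)


def decomposition_means(I1: Interval, I2: Interval,
                        params: BIParams) -> tuple[float, float, float]:
    """Means of the independent Poisson decomposition of (S(I1), S(I2)).

    For disjoint ordered windows I1 = (a, b), I2 = (c, d):
    ``S(I1) = K + T(I1 \\ I2)`` and ``S(I2) = K + T(I2 \\ I1)`` where K
    counts families observable in both windows and the T's families
    observable in exactly one; the three are independent Poissons with

    - ``E K   = theta log[(e^b - e^a + 1)(e^d - e^c + 1) / (e^d - e^c + e^b - e^a + 1)]``
    - ``E T1  = theta log[(e^d - e^c + e^b - e^a + 1) / (e^d - e^c + 1)]``
    - ``E T2  = theta log[(e^d - e^c + e^b - e^a + 1) / (e^b - e^a + 1)]``

    so ``E K + E T1 = E S(I1)`` and ``E K + E T2 = E S(I2)`` exactly.
    """
    if not (I1.a < I1.b <= I2.a < I2.b):
        raise ValueError(f"need ordered disjoint windows, got I1={I1}, I2={I2}")
    th, a, b, c, d = _scaled(params, I1.a, I1.b, I2.a, I2.b)
    w1 = _log_w1(b, a)                       # log(e^b - e^a + 1)
    w2 = _log_w1(d, c)                       # log(e^d - e^c + 1)
    w12 = _log_comb([d, c, b, a, 0.0], [1, -1, 1, -1, 1])
    ek = th * (w1 + w2 - w12)
    et1 = th * (w12 - w2)
    et2 = th * (w12 - w1)
    return ek, et1, et2


def mean_observed(a: float, b: float, params: BIParams) -> float:
    """``E S(a, b) = theta * log(e^b - e^a + 1)`` (scaled clock).

    S(a, b) is Poisson; for ``a = 0`` the mean is exactly ``theta * b``.
    """
    if not 0 <= a < b:
        raise ValueError(f"need 0 <= a < b, got ({a}, {b})")
    th, a_, b_ = _scaled(params, a, b)
    return th * _log_w1(b_, a_)


def cov_observed(I1: Interval, I2: Interval, params: BIParams) -> float:
    """``Cov(S(I1), S(I2))`` for disjoint ordered windows.

    Equals ``Var K = E K`` of :func:`decomposition_means` (the shared
    Poisson component carries all of the dependence); non-negative.
    """
    return decomposition_means(I1, I2, params)[0]


# ---------------------------------------------------------------------------
# expected sample variance of the per-window counts
# ---------------------------------------------------------------------------

def expected_sample_variance(partition: TimePartition, params: BIParams) -> float:
    """Exact ``E V_p`` for the counts S_1..S_p over an arbitrary partition.

    ``V_p = (1/(p(p-1))) sum_{i<j} (S_i - S_j)^2`` and

    ``E V_p = (1/(p(p-1))) sum_{i<j} { theta log[(w_i + w_j + 1)^2 /
    ((w_i + 1)(w_j + 1))] + theta^2 log^2[(w_i + 1)/(w_j + 1)] }``

    with ``w_i = e^{t_i} - e^{t_{i-1}}`` on the scaled clock.
    """
    p = partition.p
    if p < 2:
        raise ValueError(f"need at least 2 windows, got p={p}")
    th = params.theta_scaled
    t = params.scale_time(partition.points)
    # log(w_i + 1) and pairwise log(w_i + w_j + 1), all via signed logsumexp
    lw1 = np.array([_log_w1(t[i + 1], t[i]) for i in range(p)])
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            lwij = _log_comb([t[j + 1], t[j], t[i + 1], t[i], 0.0],
                             [1, -1, 1, -1, 1])
            total += th * (2 * lwij - lw1[i] - lw1[j]) + th ** 2 * (lw1[i] - lw1[j]) ** 2
    return total / (p * (p - 1))


def equal_intervals_esv(tau: float, p: int, params: BIParams) -> float:
    """Exact ``E V_p`` for p equal-length windows on (0, tau).

    Evaluates the equal-partition double sum with ``gamma = e^{lam*tau/p}``
    and ``theta`` replaced by ``theta/lam``; agrees with
    :func:`expected_sample_variance` on ``TimePartition.equal`` to machine
    precision.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if p < 2:
        raise ValueError(f"need at least 2 windows, got p={p}")
    th = params.theta_scaled
    u = params.lam * tau / p  # log gamma
    idx = np.arange(p)
    lw1 = np.array([_log_comb([(i + 1) * u, i * u, 0.0], [1, -1, 1]) for i in idx])
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            lwij = _log_comb([(j + 1) * u, j * u, (i + 1) * u, i * u, 0.0],
                             [1, -1, 1, -1, 1])
            total += th * (2 * lwij - lw1[i] - lw1[j]) + th ** 2 * (lw1[i] - lw1[j]) ** 2
    return total / (p * (p - 1))


def log_intervals_esv(tau: float, p: int, params: BIParams) -> float:
    """Exact ``E V_p`` for p logarithmically equal windows on (0, tau).

    With ``gamma_tilde = (e^{lam*tau} - 1)/p`` the counts are i.i.d.
    Poisson and ``E V_p = (theta/lam) * log[(2 gamma_tilde + 1) /
    (gamma_tilde + 1)]``; tends to ``(theta/lam) * log 2`` as
    ``gamma_tilde -> inf`` and to 0 as ``lam -> inf``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if p < 2:
        raise ValueError(f"need at least 2 windows, got p={p}")
    th = params.theta_scaled
    lg = params.lam * tau - np.log(p) + np.log1p(-np.exp(-params.lam * tau))  # log gamma_tilde
    num = _log_comb([np.log(2.0) + lg, 0.0], [1, 1])
    den = _log_comb([lg, 0.0], [1, 1])
    return th * (num - den)


def correlation_log_equal(gamma: float) -> float:
    """Correlation of S_i, S_j (i != j) under log-equal windows.

    ``rho = 2 - log(2*gamma + 1)/log(gamma + 1)``; in (0, 1) for gamma > 0,
    tending to 0 as gamma -> 0+ and to 1 as gamma -> inf.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return 2.0 - np.log1p(2.0 * gamma) / np.log1p(gamma)


# ---------------------------------------------------------------------------
# Ewens Sampling Formula
# ---------------------------------------------------------------------------

_ESF_ENUM_CAP = 20


def esf_pmf(counts: CountsOfCounts | Sequence[int], theta: float) -> float:
    """Ewens Sampling Formula probability of a counts-of-counts vector.

    ``P(c) = (n! / theta_(n)) * prod_j (theta/j)^{c_j} / c_j!`` with
    ``theta_(n) = theta (theta+1) ... (theta+n-1)``; sums to 1 over the
    partitions of n. Rising factorials go through log-gamma so large n is
    safe.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if not isinstance(counts, CountsOfCounts):
        counts = CountsOfCounts(counts)
    n = counts.n
    if n < 1:
        raise ValueError("counts-of-counts must describe at least one individual")
    logp = gammaln(n + 1) - (gammaln(theta + n) - gammaln(theta))
    for j, c in enumerate(counts.counts, start=1):
        if c:
            logp += c * (math.log(theta) - math.log(j)) - gammaln(c + 1)
    return float(np.exp(logp))


def iter_counts_of_counts(n: int) -> Iterator[CountsOfCounts]:
    """Enumerate all counts-of-counts vectors with ``sum_j j*c_j = n``.

    One per integer partition of n; capped at n <= 20 (the number of
    partitions grows super-polynomially).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > _ESF_ENUM_CAP:
        raise ValueError(f"partition enumeration capped at n <= {_ESF_ENUM_CAP}")
    for part in _sympy_partitions(n):
        m = max(part)
        c = [0] * m
        for size, mult in part.items():
            c[size - 1] = mult
        yield CountsOfCounts(c)
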