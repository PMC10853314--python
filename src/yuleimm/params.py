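"""Domain types for the linear birth process with immigration (BI process).

The model: new families are founded at the points of a homogeneous Poisson
process of rate ``theta`` per unit time; once founded, a family grows as a
linear pure-birth (Yule) process in which every current member gives birth
at per-capita rate ``lam``.  All closed forms in :mod:`yuleimm.analytic` are
derived for ``lam = 1``; a general birth rate is handled everywhere by the
rescaling ``t -> lam * t``, ``theta -> theta / lam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BIParams",
    "Interval",
    "TimePartition",
    "CountsOfCounts",
]


@dataclass(frozen=True)
class BIParams:
    """Rates of the BI process.

    Parameters
    ----------
    theta : float
        Immigration (family founding) rate, per unit time. Must be positive.
        In genetics settings this is the compound mutation parameter of the
        Ewens Sampling Formula.
    lam : float, default 1.0
        Per-capita birth rate, per unit time. Must be positive.

    Notes
    -----
    Every closed form in this package is stated for ``lam = 1``; general
    rates are obtained by replacing ``t`` with ``lam * t`` and ``theta``
    with ``theta / lam``. The :meth:`scaled` helper applies exactly that
    substitution.
    """

    theta: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not (self.lam > 0):
            raise ValueError(f"lam must be > 0, got {self.lam}")

    @property
    def theta_scaled(self) -> float:
        """theta / lam — the immigration rate on the unit-birth-rate clock."""
        return self.theta / self.lam

    def scale_time(self, t):
        """Map wall-clock time(s) to the unit-birth-rate clock (``lam * t``)."""
        return self.lam * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class Interval:
    """A time window ``(a, b)`` with ``0 <= a <= b``.

    Windows are open intervals; event times are continuous so endpoint
    membership is measure-zero. Degenerate windows (``a == b``) may be
    constructed, but most operations reject them unless they explicitly
    document the limit.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"interval start must be >= 0, got {self.a}")
        if self.b < self.a:
            raise ValueError(f"interval must have a <= b, got ({self.a}, {self.b})")

    @property
    def length(self) -> float:
        return self.b - self.a

    @property
    def degenerate(self) -> bool:
        return self.b == self.a


class TimePartition:
    """Strictly increasing time points ``0 = t_0 < t_1 < ... < t_p``.

    The ``p`` windows ``(t_{i-1}, t_i)`` define the sequential samples: the
    i-th sample is the set of families observable in window ``i``.

    Three named constructors cover the partitions studied in the theory:

    - :meth:`equal` — windows of equal wall-clock length ``tau / p``;
    - :meth:`log_equal` — windows with ``exp(lam*t_i) - exp(lam*t_{i-1})``
      constant, which makes the per-window observable-family counts
      identically distributed;
    - :meth:`fisher` — window boundaries matching expected cumulative
      sample sizes ``l_i``, i.e. ``t_i = log((theta + l_i)/theta)``.
    """

    def __init__(self, points: Sequence[float] | np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("a partition needs at least two time points")
        if pts[0] != 0.0:
            raise ValueError(f"first time point must be exactly 0, got {pts[0]}")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("time points must be strictly increasing")
        self.points = pts

    @property
    def p(self) -> int:
        """Number of windows."""
        return self.points.size - 1

    @property
    def horizon(self) -> float:
        return float(self.points[-1])

    @property
    def deltas(self) -> np.ndarray:
        """Window lengths ``t_i - t_{i-1}``."""
        return np.diff(self.points)

    def windows(self) -> list[Interval]:
        return [Interval(float(a), float(b)) for a, b in zip(self.points[:-1], self.points[1:])]

    @classmethod
    def equal(cls, tau: float, p: int, lam: float = 1.0) -> "TimePartition":
        """p windows of equal length on ``(0, tau)``: ``t_i = i*tau/p``."""
        if tau <= 0:
            raise ValueError("tau must be > 0")
        if p < 1:
            raise ValueError("p must be >= 1")
        return cls(np.arange(p + 1) * (tau / p))

    @classmethod
    def log_equal(cls, tau: float, p: int, lam: float = 1.0) -> "TimePartition":
        """Logarithmically equal windows on ``(0, tau)``.

        ``r_i = (1/lam) * log(i*(e^{lam*tau} - 1)/p + 1)``, so that
        ``e^{lam*r_i} - e^{lam*r_{i-1}}`` is the constant
        ``gamma_tilde = (e^{lam*tau} - 1)/p``.
        """
        if tau <= 0:
            raise ValueError("tau must be > 0")
        if p < 1:
            raise ValueError("p must be >= 1")
        gamma_tilde = np.expm1(lam * tau) / p
        i = np.arange(p + 1)
        pts = np.log1p(i * gamma_tilde) / lam
        pts[0] = 0.0
        pts[-1] = tau  # exact endpoints, immune to round-off
        return cls(pts)

    @classmethod
    def fisher(cls, sizes: Iterable[int], theta: float) -> "TimePartition":
        """Boundaries matching expected cumulative sample sizes.

        With ``l_i = n_1 + ... + n_i`` the boundary ``t_i`` solves
        ``E Z(t_i) = theta*(e^{t_i} - 1) = l_i`` (unit birth rate), giving
        ``t_i = log((theta + l_i)/theta)``.
        """
        if theta <= 0:
            raise ValueError("theta must be > 0")
        n = np.asarray(list(sizes), dtype=float)
        if n.size < 1 or np.any(n < 1):
            raise ValueError("sample sizes must be positive integers")
        l = np.concatenate([[0.0], np.cumsum(n)])
        return cls(np.log((theta + l) / theta))


@dataclass(frozen=True)
class CountsOfCounts:
    """Counts-of-counts vector ``(c_1, c_2, ..., c_m)``.

    ``c_j`` is the number of families of size ``j``; the implied sample
    size is ``n = sum_j j * c_j``. This is the state of the family-size
    process and the support of the Ewens Sampling Formula.
    """

    counts: tuple[int, ...]

    def __init__(self, counts: Iterable[int]):
        c = tuple(int(x) for x in counts)
        if any(x < 0 for x in c):
            raise ValueError("counts-of-counts entries must be non-negative")
        # drop trailing zeros so equal partitions compare equal
        while c and c[-1] == 0:
            c = c[:-1]
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        """Total number of individuals, ``sum_j j * c_j``."""
        return sum((j + 1) * c for j, c in enumerate(self.counts))

    @property
    def num_families(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_sizes(cls, sizes: Iterable[int]) -> "CountsOfCounts":
        """Build from a list of family sizes."""
        sizes = [int(s) for s in sizes]
        if any(s < 1 for s in sizes):
            raise ValueError("family sizes must be >= 1")
        m = max(sizes, default=0)
        c = [0] * m
        for s in sizes:
            c[s - 1] += 1
        return cls(c)

    def sizes(self) -> list[int]:
        """Sorted family sizes (descending)."""
        out: list[int] = []
        for j, c in enumerate(self.counts):
            out.extend([j + 1] * c)
        return sorted(out, reverse=True)
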