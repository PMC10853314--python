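"""Estimators of the immigration rate theta and birth rate lambda.

Two routes:

- the Watterson-type estimator ``theta_S = S_bar / log(1 + gamma)`` from
  counts over logarithmically equal windows (unbiased; its variance does
  not vanish as the number of windows grows, because the per-window counts
  stay correlated);

- a per-window method-of-moments system: a window ``(t_{i-1}, t_i)`` with
  observed family count ``S_hat`` and individual count ``N_hat`` satisfies,
  in expectation and with ``u = e^{lam*t_i} - e^{lam*t_{i-1}}``,

      S_hat = (theta/lam) * log(u + 1),      N_hat = (theta/lam) * u.

  The ratio ``N_hat/S_hat = u/log(u + 1)`` is strictly increasing in u, so
  u is unique whenever the ratio exceeds 1; lam then solves the strictly
  monotone boundary equation and ``theta = lam * N_hat / u``. One
  ``(theta_hat_i, lambda_hat_i)`` pair per window, aggregated by their
  means, with the sample variances across windows as dispersion proxies.

The moment system is wrapped in a model/results pair:
``SequentialCountsModel.from_csv(path).fit().summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import BIParams
from .simulate import ObservedCounts

__all__ = [
    "EstimationError",
    "NoInformationError",
    "InfeasibleError",
    "IntervalObservation",
    "EstimateSet",
    "watterson_theta",
    "watterson_theta_variance",
    "forward_moments",
    "solve_moment_system",
    "aggregate_estimates",
    "SequentialCountsModel",
    "SequentialCountsResults",
]

_RATIO_FLOOR = 1.0 + 1e-9  # below this, N_hat/S_hat carries no growth signal


class EstimationError(ValueError):
    """A window's observations do not identify (theta, lambda)."""


class NoInformationError(EstimationError):
    """No families observed in the window (S_hat = 0)."""


class InfeasibleError(EstimationError):
    """N_hat/S_hat <= 1: no positive (theta, lambda) solves the system."""


@dataclass(frozen=True)
class IntervalObservation:
    """Observed counts for one window.

    S_hat: number of distinct families observed in the window;
    N_hat: number of individuals (arrival + birth events) observed there.
    ``N_hat < S_hat`` is suspicious (each observed family contributes at
    least one event) and triggers a warning, not an error.
    """

    t_start: float
    t_end: float
    S_hat: float
    N_hat: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"need 0 <= t_start < t_end, got ({self.t_start}, {self.t_end})")
        if self.S_hat < 0 or self.N_hat < 0:
            raise ValueError("counts must be non-negative")
        if 0 < self.N_hat < self.S_hat:
            warnings.warn("N_hat < S_hat: every observed family should contribute "
                          "at least one individual", stacklevel=2)


@dataclass(frozen=True)
class EstimateSet:
    """Per-window estimates and their aggregates."""

    theta_hats: np.ndarray
    lambda_hats: np.ndarray
    theta_bar: float
    lambda_bar: float
    theta_var: float | None
    lambda_var: float | None


def watterson_theta(counts: ObservedCounts | Sequence[float], gamma: float) -> float:
    """Watterson-type estimator ``S_bar / log(1 + gamma)``.

    Valid for counts from logarithmically equal windows with
    ``e^{t_i} = i*gamma + 1``; unbiased for theta (each count is Poisson
    with mean ``theta * log(1 + gamma)``).
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    s = counts.counts if isinstance(counts, ObservedCounts) else np.asarray(counts, float)
    return float(np.mean(s) / np.log1p(gamma))


def watterson_theta_variance(theta: float, gamma: float, p: int) -> float:
    """Exact variance of the Watterson-type estimator over p windows.

    ``Var theta_S = theta/(p log(1+gamma)) * (1 + (p-1) rho)`` with
    ``rho = 2 - log(2 gamma + 1)/log(gamma + 1)``; tends to the non-zero
    ``theta*rho/log(1+gamma)`` as p grows (the windows stay correlated).
    """
    from .analytic import correlation_log_equal

    rho = correlation_log_equal(gamma)
    return theta / (p * np.log1p(gamma)) * (1.0 + (p - 1) * rho)


def forward_moments(theta: float, lam: float, t_start: float,
                    t_end: float) -> tuple[float, float]:
    """Expected (S, N) for a window under given rates.

    ``E S = (theta/lam) log(u + 1)`` and ``E N = (theta/lam) u`` with
    ``u = e^{lam*t_end} - e^{lam*t_start}``. The exact inverse of
    :func:`solve_moment_system`.
    """
    u = np.exp(lam * t_end) - np.exp(lam * t_start)
    return theta / lam * float(np.log1p(u)), theta / lam * float(u)


def _solve_u(ratio: float) -> float:
    """Invert the strictly increasing ``u / log(1 + u)`` at ``ratio > 1``."""
    f = lambda u: u / np.log1p(u) - ratio
    lo = ratio - 1.0  # u ~ 2(ratio-1) near the boundary, so this under-shoots
    while f(lo) > 0:
        lo /= 8.0
    hi = max(4.0 * (ratio - 1.0), 1.0)
    while f(hi) < 0:
        hi *= 8.0
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200))


def _solve_lam(u: float, t_start: float, t_end: float) -> float:
    """Solve ``e^{lam*t_end} - e^{lam*t_start} = u`` for lam > 0.

    The left side is strictly increasing in lam and tends to 0 as
    lam -> 0+. Solved on the log scale,
    ``h(lam) = lam*t_end + log(1 - e^{-lam*(t_end - t_start)}) - log u``,
    to stay finite for large lam; bracket auto-expands.
    """
    if t_start == 0.0:
        return float(np.log1p(u) / t_end)
    logu = np.log(u)
    h = lambda lam: lam * t_end + np.log1p(-np.exp(-lam * (t_end - t_start))) - logu
    lo = 1e-10
    while h(lo) > 0:
        lo /= 8.0
    hi = max((logu + 1.0) / t_end, 1.0)
    while h(hi) < 0:
        hi *= 2.0
    return float(brentq(h, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200))


def solve_moment_system(obs: IntervalObservation) -> tuple[float, float]:
    """Per-window moment estimates ``(theta_hat, lambda_hat)``.

    Solves ``S_hat = (theta/lam) log(u+1)``, ``N_hat = (theta/lam) u``.
    Exact (to root tolerance ~1e-10) when the inputs are the analytic
    means. Raises :class:`NoInformationError` when ``S_hat = 0`` and
    :class:`InfeasibleError` when ``N_hat/S_hat <= 1``.
    """
    if obs.S_hat == 0:
        raise NoInformationError("S_hat = 0: window carries no information")
    ratio = obs.N_hat / obs.S_hat
    if ratio < _RATIO_FLOOR:
        raise InfeasibleError(
            f"N_hat/S_hat = {ratio:.6g} <= 1: no positive solution (the system "
            "needs more individuals than families)")
    u = _solve_u(ratio)
    lam = _solve_lam(u, obs.t_start, obs.t_end)
    theta = lam * obs.N_hat / u
    return float(theta), float(lam)


def aggregate_estimates(per_interval: Iterable[tuple[float, float]]) -> EstimateSet:
    """Combine per-window estimates into means and sample variances.

    The sample variance (denominator p-1) is ``None`` for a single window.
    """
    pairs = list(per_interval)
    if not pairs:
        raise ValueError("need at least one per-interval estimate")
    th = np.asarray([p[0] for p in pairs], dtype=float)
    la = np.asarray([p[1] for p in pairs], dtype=float)
    tv = float(np.var(th, ddof=1)) if th.size > 1 else None
    lv = float(np.var(la, ddof=1)) if la.size > 1 else None
    return EstimateSet(th, la, float(th.mean()), float(la.mean()), tv, lv)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class SequentialCountsModel:
    """Method-of-moments model for per-window (S_hat, N_hat) observations.

    Construct from a list of :class:`IntervalObservation`, a DataFrame
    with columns ``t_start, t_end, S_hat, N_hat`` (:meth:`from_dataframe`)
    or a CSV with that header (:meth:`from_csv`); :meth:`fit` solves each
    window independently, drops unidentifiable windows with a warning, and
    returns a :class:`SequentialCountsResults`.
    """

    def __init__(self, observations: Sequence[IntervalObservation]):
        obs = list(observations)
        if not obs:
            raise ValueError("need at least one interval observation")
        self.observations = obs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SequentialCountsModel":
        required = ["t_start", "t_end", "S_hat", "N_hat"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls([IntervalObservation(float(r.t_start), float(r.t_end),
                                        float(r.S_hat), float(r.N_hat))
                    for r in df.itertuples()])

    @classmethod
    def from_csv(cls, path) -> "SequentialCountsModel":
        return cls.from_dataframe(pd.read_csv(path))

    def fit(self) -> "SequentialCountsResults":
        estimates, used, skipped = [], [], []
        for i, obs in enumerate(self.observations):
            try:
                estimates.append(solve_moment_system(obs))
                used.append(i)
            except EstimationError as err:
                skipped.append((i, str(err)))
                warnings.warn(f"window {i} ({obs.t_start}, {obs.t_end}) skipped: {err}",
                              stacklevel=2)
        if not estimates:
            raise InfeasibleError("no window yielded a feasible estimate")
        return SequentialCountsResults(self, aggregate_estimates(estimates),
                                       used, skipped)


class SequentialCountsResults:
    """Fitted per-window and aggregated (theta, lambda) estimates.

    Attributes
    ----------
    estimates : EstimateSet
        Per-window estimates over the usable windows, their means
        (``theta_bar``, ``lambda_bar``) and sample variances.
    used, skipped : lists
        Indices of windows that entered the fit; skipped windows with the
        reason each was dropped.
    """

    def __init__(self, model: SequentialCountsModel, estimates: EstimateSet,
                 used: list[int], skipped: list[tuple[int, str]]):
        self.model = model
        self.estimates = estimates
        self.used = used
        self.skipped = skipped

    @property
    def theta_bar(self) -> float:
        return self.estimates.theta_bar

    @property
    def lambda_bar(self) -> float:
        return self.estimates.lambda_bar

    @property
    def params(self) -> BIParams:
        """The aggregated rates as a BIParams (convenience for simulation)."""
        return BIParams(theta=self.theta_bar, lam=self.lambda_bar)

    def to_frame(self) -> pd.DataFrame:
        """Per-window estimates, one row per usable window."""
        obs = [self.model.observations[i] for i in self.used]
        return pd.DataFrame({
            "window": self.used,
            "t_start": [o.t_start for o in obs],
            "t_end": [o.t_end for o in obs],
            "S_hat": [o.S_hat for o in obs],
            "N_hat": [o.N_hat for o in obs],
            "theta_hat": self.estimates.theta_hats,
            "lambda_hat": self.estimates.lambda_hats,
        })

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Sequential counts moment estimation",
            "===================================",
            f"windows used: {len(self.used)}   skipped: {len(self.skipped)}",
            "",
            f"{'':<12}{'estimate':>12}{'sample var':>14}",
            f"{'theta':<12}{est.theta_bar:>12.6g}"
            f"{est.theta_var if est.theta_var is not None else float('nan'):>14.6g}",
            f"{'lambda':<12}{est.lambda_bar:>12.6g}"
            f"{est.lambda_var if est.lambda_var is not None else float('nan'):>14.6g}",
        ]
        if self.skipped:
            lines.append("")
            for i, reason in self.skipped:
                lines.append(f"  window {i} skipped: {reason}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<SequentialCountsResults theta_bar={self.theta_bar:.4g} "
                f"lambda_bar={self.lambda_bar:.4g} windows={len(self.used)}>")
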