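"""Exact simulation of the BI process and of its jump chain (the CRP).

Two complementary samplers are provided:

- :func:`simulate_bi` generates a full event-level realization (every
  family's founding time and all of its birth times), suitable whenever
  the expected population ``(theta/lam) e^{lam*tau}`` is modest. Families
  are simulated independently: founding times are uniform order statistics
  of a Poisson number of arrivals, and within a family the gap to the next
  birth from size k is Exponential(k*lam).

- :func:`sample_window_counts` draws the per-window observable-family
  counts directly by propagating each family's size across the window
  boundaries with the exact Yule transition law (geometric initial size,
  negative-binomial growth). This samples the exact finite-dimensional
  distribution without enumerating birth events, so horizons with
  ``lam*tau`` in the tens remain cheap; it is the workhorse behind the
  Monte-Carlo expected-sample-variance estimates.

The Chinese Restaurant Process jump chain and the discretization of a
realization into its first-n-individuals counts-of-counts are also here,
for the distributional embedding checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import BIParams, CountsOfCounts, TimePartition

__all__ = [
    "FamilyTrajectory",
    "PopulationRealization",
    "ObservedCounts",
    "simulate_bi",
    "count_observed",
    "sample_window_counts",
    "sample_family_table",
    "empirical_esv",
    "simulate_crp",
    "sample_crp_sizes",
    "jump_counts",
    "sample_jump_counts",
    "sample_conditional_counts",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# event-level realization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTrajectory:
    """One family: its founding time and its (strictly increasing) birth times.

    The founding arrival is the family's first event but is not itself a
    birth; the family's size at time t >= arrival is 1 + #births <= t.
    """

    arrival: float
    births: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.births, dtype=float)
        object.__setattr__(self, "births", b)
        if b.size and (b[0] <= self.arrival or np.any(np.diff(b) <= 0)):
            raise ValueError("births must be strictly increasing and after arrival")

    def size_at(self, t: float) -> int:
        if t < self.arrival:
            return 0
        return 1 + int(np.searchsorted(self.births, t, side="right"))

    def event_times(self) -> np.ndarray:
        """Arrival followed by births."""
        return np.concatenate([[self.arrival], self.births])


@dataclass(frozen=True)
class PopulationRealization:
    """A complete BI realization on (0, horizon]."""

    families: tuple[FamilyTrajectory, ...]
    horizon: float
    params: BIParams
    seed: object = None

    @property
    def num_families(self) -> int:
        return len(self.families)

    def popsize(self, t: float | None = None) -> int:
        """Z(t): individuals alive at time t (default: at the horizon)."""
        t = self.horizon if t is None else t
        return sum(f.size_at(t) for f in self.families)

    def counts_of_counts(self, t: float | None = None) -> CountsOfCounts:
        """Family-size counts C(t) (families founded after t are absent)."""
        t = self.horizon if t is None else t
        sizes = [f.size_at(t) for f in self.families if f.arrival <= t]
        return CountsOfCounts.from_sizes([s for s in sizes if s > 0])

    def to_frame(self) -> pd.DataFrame:
        """One row per event: family_id, event_time, event_type."""
        rows = []
        for fid, fam in enumerate(self.families):
            rows.append((fid, fam.arrival, "arrival"))
            rows.extend((fid, t, "birth") for t in fam.births)
        df = pd.DataFrame(rows, columns=["family_id", "event_time", "event_type"])
        return df.sort_values(["event_time", "family_id"], kind="stable").reset_index(drop=True)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, horizon: float,
                   params: BIParams) -> "PopulationRealization":
        fams = []
        for _, g in df.groupby("family_id"):
            arr = float(g.loc[g.event_type == "arrival", "event_time"].iloc[0])
            births = np.sort(g.loc[g.event_type == "birth", "event_time"].to_numpy(float))
            fams.append(FamilyTrajectory(arr, births))
        fams.sort(key=lambda f: f.arrival)
        return cls(tuple(fams), horizon, params)


def _yule_births(arrival: float, horizon: float, lam: float,
                 rng: np.random.Generator) -> np.ndarray:
    """All birth times of one family on (arrival, horizon].

    Gap from size k to k+1 is Exp(k*lam); cumulatively the j-th birth is
    arrival + sum_{k<=j} E_k/(k*lam) with E_k iid Exp(1). Gaps are drawn in
    geometrically growing chunks until the horizon is passed.
    """
    remaining = horizon - arrival
    if remaining <= 0:
        return np.empty(0)
    # expected total births e^{lam*remaining} - 1; start near that, extend as needed
    chunk = max(8, int(np.expm1(lam * remaining) * 1.5) + 8)
    gaps = rng.exponential(size=chunk)
    k = np.arange(1, chunk + 1, dtype=float)
    times = np.cumsum(gaps / (k * lam))
    while times[-1] <= remaining:
        more = rng.exponential(size=chunk)
        k2 = np.arange(k.size + 1, k.size + chunk + 1, dtype=float)
        times = np.concatenate([times, times[-1] + np.cumsum(more / (k2 * lam))])
        k = np.concatenate([k, k2])
        chunk *= 2
    return arrival + times[times <= remaining]


def simulate_bi(params: BIParams, horizon: float, seed=None) -> PopulationRealization:
    """Draw one event-level BI realization on (0, horizon].

    Family foundings are a Poisson(theta*horizon) process (uniform order
    statistics); each family then grows independently with Exp(k*lam) gaps.
    Deterministic given the seed.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    rng = _as_rng(seed)
    n_fam = rng.poisson(params.theta * horizon)
    arrivals = np.sort(rng.uniform(0.0, horizon, size=n_fam))
    fams = tuple(FamilyTrajectory(a, _yule_births(a, horizon, params.lam, rng))
                 for a in arrivals)
    return PopulationRealization(fams, horizon, params, seed=seed)


# ---------------------------------------------------------------------------
# observable-family counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservedCounts:
    """Per-window observable-family counts S_1, ..., S_p.

    A family is observable in a window if it has at least one event there —
    a birth, or its founding arrival (the decomposition
    ``S(a,b) = U_{(0,a)}((a,b)) + X((a,b))`` counts founding arrivals as
    the family's first observable event). A family may be observable in
    several windows.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def p(self) -> int:
        return self.counts.size

    def sample_variance(self) -> float:
        """``V_p = (1/(p(p-1))) sum_{i<j} (S_i - S_j)^2`` (= ddof-1 variance)."""
        if self.p < 2:
            raise ValueError("sample variance needs at least 2 windows")
        return float(np.var(self.counts, ddof=1))


def count_observed(pop: PopulationRealization,
                   partition: TimePartition) -> ObservedCounts:
    """Count observable families per window of the partition.

    Windows are half-open ``[t_{i-1}, t_i)`` for determinism; the partition
    must not exceed the realization's horizon.
    """
    if partition.horizon > pop.horizon + 1e-12:
        raise ValueError("partition exceeds the simulation horizon")
    p = partition.p
    counts = np.zeros(p, dtype=np.int64)
    edges = partition.points
    for fam in pop.families:
        ev = fam.event_times()
        w = np.searchsorted(edges, ev, side="right") - 1
        w = np.unique(w[(w >= 0) & (w < p)])
        counts[w] += 1
    return ObservedCounts(counts)


# ---------------------------------------------------------------------------
# window-skeleton sampler (exact finite-dimensional law, no event lists)
# ---------------------------------------------------------------------------

def sample_window_counts(params: BIParams, partition: TimePartition,
                         reps: int, seed=None) -> np.ndarray:
    """Draw ``reps`` replicates of (S_1, ..., S_p) exactly.

    Works on the scaled clock: each family's size at the end of its arrival
    window is geometric with parameter ``e^{-(t_end - x)}``, and across a
    later window of scaled length ``delta`` a size-k family gains a
    negative-binomial ``NB(k, e^{-delta})`` number of births. A family is
    observable in its arrival window (the arrival is an event) and in any
    window where its size strictly increases. Returns an int array of shape
    ``(reps, p)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _as_rng(seed)
    t = params.scale_time(partition.points)
    tp, p = t[-1], partition.p
    th = params.theta_scaled

    n_fam = rng.poisson(th * tp, size=reps)
    total = int(n_fam.sum())
    rep_id = np.repeat(np.arange(reps), n_fam)
    x = rng.uniform(0.0, tp, size=total)
    w0 = np.searchsorted(t, x, side="right") - 1  # arrival window, 0..p-1

    S = np.zeros((reps, p), dtype=np.int64)
    np.add.at(S, (rep_id, w0), 1)  # arrival event => observable there

    size = rng.geometric(np.exp(-(t[w0 + 1] - x))).astype(np.int64)
    for w in range(1, p):
        alive = w0 < w
        if not alive.any():
            continue
        k = size[alive]
        growth = rng.negative_binomial(k, np.exp(-(t[w + 1] - t[w])))
        grew = growth > 0
        np.add.at(S, (rep_id[alive][grew], w), 1)
        size[alive] = k + growth
    return S


def sample_family_table(params: BIParams, boundaries: Sequence[float],
                        reps: int, seed=None):
    """Per-family arrival data and per-segment birth indicators.

    ``boundaries`` is an increasing grid starting at 0 that cuts the
    horizon into segments. For every family of every replicate the exact
    skeleton (geometric size at the end of the arrival segment,
    negative-binomial growth across later segments) is drawn, recording
    whether the family had >= 1 birth in each segment.

    Returns ``(rep_id, arrival, seg0, grew)``: replicate index, arrival
    time (wall clock), index of the arrival segment, and a boolean
    ``(families, segments)`` matrix of birth indicators. This is the raw
    material for Monte-Carlo checks of the marked-Poisson observable /
    unobservable family counts.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size < 2 or b[0] != 0 or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be an increasing grid starting at 0")
    rng = _as_rng(seed)
    t = params.lam * b
    tp = t[-1]
    n_seg = t.size - 1
    th = params.theta_scaled

    n_fam = rng.poisson(th * tp, size=reps)
    total = int(n_fam.sum())
    rep_id = np.repeat(np.arange(reps), n_fam)
    x = rng.uniform(0.0, tp, size=total)
    seg0 = np.searchsorted(t, x, side="right") - 1

    grew = np.zeros((total, n_seg), dtype=bool)
    size = rng.geometric(np.exp(-(t[seg0 + 1] - x))).astype(np.int64)
    grew[np.arange(total), seg0] = size > 1
    for s in range(1, n_seg):
        alive = seg0 < s
        if not alive.any():
            continue
        growth = rng.negative_binomial(size[alive], np.exp(-(t[s + 1] - t[s])))
        grew[alive, s] = growth > 0
        size[alive] += growth
    return rep_id, x / params.lam, seg0, grew


def empirical_esv(params: BIParams, partition: TimePartition,
                  reps: int, seed=None) -> tuple[float, float]:
    """Monte-Carlo mean of the sample variance V_p, with its standard error.

    Each replicate draws (S_1, ..., S_p) via :func:`sample_window_counts`
    and computes ``V_p = (1/(p(p-1))) sum_{i<j} (S_i - S_j)^2``; returns
    ``(mean over replicates, standard error of that mean)``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if partition.p < 2:
        raise ValueError("need at least 2 windows")
    S = sample_window_counts(params, partition, reps, seed)
    v = np.var(S, axis=1, ddof=1)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(reps))


# ---------------------------------------------------------------------------
# CRP jump chain
# ---------------------------------------------------------------------------

def sample_crp_sizes(n: int, theta: float, reps: int, seed=None) -> np.ndarray:
    """Family sizes after n CRP arrivals, for ``reps`` independent runs.

    Arrival m+1 founds a new family with probability ``theta/(m + theta)``,
    otherwise joins the family of a uniformly chosen previous arrival
    (i.e. proportionally to family size). Returns an int array of shape
    ``(reps, n)`` of per-run family sizes sorted descending, zero-padded.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    rng = _as_rng(seed)
    labels = np.zeros((reps, n), dtype=np.int32)
    n_open = np.ones(reps, dtype=np.int32)  # first arrival founds family 0
    rows = np.arange(reps)
    for m in range(1, n):
        r = rng.uniform(0.0, m + theta, size=reps)
        new = r >= m
        join = ~new
        prev = np.minimum(r[join].astype(np.int64), m - 1)
        labels[join, m] = labels[rows[join], prev]
        labels[new, m] = n_open[new]
        n_open[new] += 1
    sizes = np.zeros((reps, n), dtype=np.int64)
    np.add.at(sizes, (np.repeat(rows, n), labels.ravel()), 1)
    return -np.sort(-sizes, axis=1)  # descending per row


def simulate_crp(n: int, theta: float, seed=None) -> CountsOfCounts:
    """One CRP run of n arrivals; returns its counts-of-counts (ESF law)."""
    sizes = sample_crp_sizes(n, theta, 1, seed)[0]
    return CountsOfCounts.from_sizes(sizes[sizes > 0])


# ---------------------------------------------------------------------------
# discretization of a realization: first-n-individuals counts
# ---------------------------------------------------------------------------

def jump_counts(pop: PopulationRealization, n: int) -> CountsOfCounts:
    """Counts-of-counts among the first n individuals of a realization.

    Founders and births are pooled in event-time order (ties are
    measure-zero and broken by family index); the first n events define n
    individuals whose family-size counts are returned. This discretization
    of the BI process is distributed as the CRP jump chain, independently
    of the event times. Raises if the realization contains fewer than n
    individuals.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    times, fams = [], []
    for fid, fam in enumerate(pop.families):
        ev = fam.event_times()
        times.append(ev)
        fams.append(np.full(ev.size, fid))
    if not times:
        raise ValueError("realization has no individuals")
    times = np.concatenate(times)
    fams = np.concatenate(fams)
    if times.size < n:
        raise ValueError(f"realization has {times.size} individuals, need {n}; "
                         "enlarge the horizon")
    order = np.lexsort((fams, times))[:n]
    sizes = np.bincount(fams[order])
    return CountsOfCounts.from_sizes(sizes[sizes > 0])


def sample_jump_counts(params: BIParams, n: int, reps: int, seed=None,
                       horizon: float | None = None) -> np.ndarray:
    """Batch sampler for the first-n-individuals family sizes.

    Vectorized equivalent of running :func:`simulate_bi` +
    :func:`jump_counts` ``reps`` times: only each family's founding time
    and first n-1 birth times are generated, since later births cannot be
    among the first n events. Replicates whose realization holds fewer
    than n individuals by the horizon are dropped — legitimate, because
    the jump-chain law is independent of the population-size process, so
    conditioning on {Z(horizon) >= n} does not change it. Returns family
    sizes sorted descending, shape ``(kept_reps, n)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    th, lam = params.theta_scaled, params.lam
    if horizon is None:
        # scaled horizon with E Z comfortably above n
        hs = float(np.log1p((3.0 * n + 10.0) / th))
    else:
        hs = lam * horizon

    n_fam = rng.poisson(th * hs, size=reps)
    total = int(n_fam.sum())
    rep_id = np.repeat(np.arange(reps), n_fam)
    x = rng.uniform(0.0, hs, size=total)

    # first n-1 birth times per family (scaled clock)
    k = np.arange(1, n, dtype=float)
    gaps = rng.exponential(size=(total, n - 1)) / k if n > 1 else np.empty((total, 0))
    btimes = x[:, None] + np.cumsum(gaps, axis=1)

    ev_time = np.concatenate([x[:, None], btimes], axis=1).ravel()
    ev_rep = np.repeat(rep_id, n)
    ev_fam = np.repeat(np.arange(total), n)
    keep = ev_time <= hs
    ev_time, ev_rep, ev_fam = ev_time[keep], ev_rep[keep], ev_fam[keep]

    order = np.lexsort((ev_fam, ev_time, ev_rep))
    ev_rep, ev_fam = ev_rep[order], ev_fam[order]
    counts_per_rep = np.bincount(ev_rep, minlength=reps)
    offsets = np.concatenate([[0], np.cumsum(counts_per_rep)])

    out = []
    for r in range(reps):
        if counts_per_rep[r] < n:
            continue
        fam_ids = ev_fam[offsets[r]:offsets[r] + n]
        sizes = np.bincount(np.searchsorted(np.unique(fam_ids), fam_ids))
        row = np.zeros(n, dtype=np.int64)
        row[:sizes.size] = -np.sort(-sizes)
        out.append(row)
    if not out:
        raise ValueError("no replicate reached n individuals; enlarge the horizon")
    return np.stack(out)


def sample_conditional_counts(theta: float, n: int, reps: int,
                              seed=None) -> np.ndarray:
    """Family sizes of C(t) conditional on Z(t) = n, by rejection.

    Uses ``t = log((n + theta)/theta)`` (unit birth rate), the choice that
    maximizes P(Z(t) = n) and whose value does not affect the conditional
    law. Each attempt draws the exact marginal C(t): a Poisson(theta*t)
    number of families with uniform founding times and geometric sizes;
    the attempt is accepted when the sizes sum to n. Returns sizes sorted
    descending, shape ``(reps, n)``.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    t = float(np.log((n + theta) / theta))
    out = np.zeros((reps, n), dtype=np.int64)
    got = 0
    batch = max(1000, reps // 2)
    while got < reps:
        n_fam = rng.poisson(theta * t, size=batch)
        total = int(n_fam.sum())
        x = rng.uniform(0.0, t, size=total)
        sizes = rng.geometric(np.exp(-(t - x)))
        rep_id = np.repeat(np.arange(batch), n_fam)
        z = np.bincount(rep_id, weights=sizes, minlength=batch).astype(np.int64)
        for r in np.nonzero(z == n)[0]:
            if got == reps:
                break
            s = sizes[rep_id == r]
            row = np.zeros(n, dtype=np.int64)
            row[:s.size] = -np.sort(-s)
            out[got] = row
            got += 1
    return out
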