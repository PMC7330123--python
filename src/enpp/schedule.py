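"""Pruning threshold schedules for exceedance-count early stopping.

A feature undergoing a permutation test accumulates *exceedances*: rounds in
which the permuted statistic is at least as extreme as the observed one.  For
a feature whose true permutation p-value equals the per-feature significance
threshold ``p_adj``, the exceedance count after ``r`` rounds is
Binomial(r, p_adj).  The schedule ``C(r)`` is, for each round, the smallest
integer count whose upper binomial tail falls at or below the pruning
significance level ``p_prun``; a feature whose cumulative count reaches
``C(r)`` at round ``r`` is judged non-significant and removed from further
rounds.

This module builds such schedules, analyses their cumulative false-pruning
risk, and round-trips them through a plain-text table format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binom

__all__ = [
    "ScheduleError",
    "SignificanceParams",
    "PruningSchedule",
    "binomial_tail",
    "cprun_at",
    "build_schedule",
    "false_prune_risk",
    "hitting_probability",
    "admissible_true_signals",
    "admissible_true_signals_from_risk",
    "write_schedule",
    "read_schedule",
]


class ScheduleError(ValueError):
    """Invalid significance parameters or schedule."""


@dataclass(frozen=True)
class SignificanceParams:
    """Significance levels driving the pruning schedule.

    Parameters
    ----------
    p_adj
        Per-feature significance threshold after multiple-testing
        correction (Bonferroni: ``p_raw / J``).
    p_prun
        Significance level of the per-round binomial pruning test.
        Defaults to ``p_adj``.
    p_raw
        Unadjusted family-wise significance level, if known.
    J
        Number of features behind the correction, if known.
    """

    p_adj: float
    p_prun: Optional[float] = None
    p_raw: Optional[float] = None
    J: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_adj <= 1.0:
            raise ScheduleError(f"p_adj must be in (0, 1], got {self.p_adj}")
        if self.p_prun is None:
            object.__setattr__(self, "p_prun", self.p_adj)
        if not 0.0 < self.p_prun <= 1.0:
            raise ScheduleError(f"p_prun must be in (0, 1], got {self.p_prun}")
        if self.p_raw is not None:
            if not self.p_adj <= self.p_raw <= 1.0:
                raise ScheduleError(
                    f"need p_adj <= p_raw <= 1, got p_adj={self.p_adj}, p_raw={self.p_raw}"
                )
        if self.J is not None and self.J < 1:
            raise ScheduleError(f"J must be a positive integer, got {self.J}")

    @classmethod
    def bonferroni(
        cls, p_raw: float, J: int, p_prun: Optional[float] = None
    ) -> "SignificanceParams":
        """Derive ``p_adj = p_raw / J`` from a family-wise level and feature count."""
        if J < 1:
            raise ScheduleError(f"J must be a positive integer, got {J}")
        return cls(p_adj=p_raw / J, p_prun=p_prun, p_raw=p_raw, J=J)


@dataclass(frozen=True)
class PruningSchedule:
    """Per-round integer pruning thresholds ``C(r)`` for rounds 1..R.

    ``thresholds[r - 1]`` is the threshold for round ``r``.  A value of
    ``r + 1`` means pruning is impossible at that round (the count can be at
    most ``r``).
    """

    params: Optional[SignificanceParams]
    R: int
    thresholds: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=np.int64)
        object.__setattr__(self, "thresholds", t)
        if self.R < 1:
            raise ScheduleError(f"R must be >= 1, got {self.R}")
        if t.shape != (self.R,):
            raise ScheduleError("thresholds must have length R")
        r = np.arange(1, self.R + 1)
        if np.any(t < 1) or np.any(t > r + 1):
            raise ScheduleError("thresholds must satisfy 1 <= C(r) <= r + 1")
        if np.any(np.diff(t) < 0):
            raise ScheduleError("thresholds must be non-decreasing")

    def __len__(self) -> int:
        return self.R

    def threshold(self, r: int) -> int:
        """Threshold for round ``r`` (1-based)."""
        if not 1 <= r <= self.R:
            raise ScheduleError(f"round must be in [1, {self.R}], got {r}")
        return int(self.thresholds[r - 1])

    @property
    def max_threshold(self) -> int:
        return int(self.thresholds.max())

    @classmethod
    def no_pruning(cls, R: int) -> "PruningSchedule":
        """A schedule with every threshold at the unattainable ``r + 1``.

        Running the engine against it reproduces a plain, unpruned
        permutation test.
        """
        thresholds = np.arange(2, R + 2, dtype=np.int64)
        return cls(params=None, R=R, thresholds=thresholds)


def binomial_tail(k: int, r: int, p: float) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(r, p).

    Uses the survival function (regularized incomplete beta) rather than
    term summation, so it stays accurate for p as small as 1e-7 with r up
    to 1e5 and beyond.
    """
    if not 0.0 < p < 1.0:
        raise ScheduleError(f"p must be in (0, 1), got {p}")
    if not 0 <= k <= r:
        raise ScheduleError(f"need 0 <= k <= r, got k={k}, r={r}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, r, p))


def cprun_at(r: int, params: SignificanceParams) -> int:
    """Smallest count k with P(X >= k) <= p_prun for X ~ Binomial(r, p_adj).

    Returns ``r + 1`` when no attainable count satisfies the pruning test
    (possible only for degenerate parameter choices with p_prun < p_adj).
    """
    if r < 1:
        raise ScheduleError(f"round must be >= 1, got {r}")
    p_adj, p_prun = params.p_adj, params.p_prun
    if binomial_tail(r, r, p_adj) > p_prun:
        return r + 1
    # tail is decreasing in k: bisect for the smallest feasible k
    lo, hi = 1, r
    while lo < hi:
        mid = (lo + hi) // 2
        if binomial_tail(mid, r, p_adj) <= p_prun:
            hi = mid
        else:
            lo = mid + 1
    return lo


def build_schedule(params: SignificanceParams, R: int) -> PruningSchedule:
    """Thresholds ``cprun_at(r, params)`` for r = 1..R.

    The threshold sequence is non-decreasing and piecewise constant with few
    distinct values, so the construction sweeps over constant segments and
    locates each breakpoint by bisection on the round index — O((max
    threshold) * log R) tail evaluations instead of O(R).
    """
    if R < 1:
        raise ScheduleError(f"R must be >= 1, got {R}")
    p_adj, p_prun = params.p_adj, params.p_prun
    thresholds = np.empty(R, dtype=np.int64)
    r, c = 1, 1
    while r <= R:
        while c <= r and binomial_tail(c, r, p_adj) > p_prun:
            c += 1
        if c > r:
            thresholds[r - 1] = r + 1  # cannot prune at this round
            r += 1
            continue
        # last round at which count c still satisfies the pruning test;
        # the tail P(X >= c) is increasing in r, so bisect
        if binomial_tail(c, R, p_adj) <= p_prun:
            r_end = R
        else:
            lo, hi = r, R  # lo feasible, hi infeasible
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if binomial_tail(c, mid, p_adj) <= p_prun:
                    lo = mid
                else:
                    hi = mid
            r_end = lo
        thresholds[r - 1 : r_end] = c
        r = r_end + 1
        c += 1
    return PruningSchedule(params=params, R=R, thresholds=thresholds)


def false_prune_risk(schedule: PruningSchedule) -> float:
    """Per-round pruning significance summed over the schedule.

    Returns ``sum_r P(X_r >= C(r))`` with ``X_r ~ Binomial(r, p_adj)``: a
    union bound on the probability that a feature whose true exceedance
    probability is exactly ``p_adj`` is ever pruned.  Rounds with the
    unattainable sentinel threshold ``r + 1`` contribute zero.
    """
    if schedule.params is None:
        raise ScheduleError("schedule has no significance parameters")
    p_adj = schedule.params.p_adj
    r = np.arange(1, schedule.R + 1)
    t = schedule.thresholds
    reachable = t <= r
    out = np.zeros(schedule.R)
    out[reachable] = binom.sf(t[reachable] - 1, r[reachable], p_adj)
    return float(out.sum())


def hitting_probability(schedule: PruningSchedule, p: Optional[float] = None) -> float:
    """Exact probability that the exceedance-count process ever hits the schedule.

    Dynamic programming over count states for a feature with per-round
    exceedance probability ``p`` (default: the schedule's ``p_adj``).  This
    is the sharp companion of :func:`false_prune_risk`, which upper-bounds it.
    """
    if p is None:
        if schedule.params is None:
            raise ScheduleError("no p given and schedule has no parameters")
        p = schedule.params.p_adj
    if not 0.0 < p < 1.0:
        raise ScheduleError(f"p must be in (0, 1), got {p}")
    t = schedule.thresholds
    K = int(t.max())
    if K > 100_000:
        raise ScheduleError("schedule thresholds too large for the hitting DP")
    # state[k]: P(alive with count == k); top bucket K saturates ("count >= K")
    state = np.zeros(K + 1)
    state[0] = 1.0
    hit = 0.0
    for r in range(1, schedule.R + 1):
        new = state * (1.0 - p)
        new[1:] += state[:-1] * p
        new[K] += state[K] * p
        c = t[r - 1]
        if c <= K:
            hit += new[c:].sum()
            new[c:] = 0.0
        state = new
    return float(hit)


def admissible_true_signals_from_risk(risk: float, p_raw: float) -> int:
    """floor(p_raw / risk): how many truly significant features the schedule
    tolerates while keeping the family-wise false-pruning probability under
    ``p_raw`` (union bound)."""
    if risk <= 0.0:
        raise ScheduleError("false-pruning risk must be positive")
    return math.floor(p_raw / risk)


def admissible_true_signals(schedule: PruningSchedule, p_raw: float) -> int:
    return admissible_true_signals_from_risk(false_prune_risk(schedule), p_raw)


def write_schedule(schedule: PruningSchedule, path) -> None:
    """Write a schedule as a two-column delimited table with a header comment."""
    params = schedule.params
    p_adj = "NA" if params is None else repr(params.p_adj)
    p_prun = "NA" if params is None else repr(params.p_prun)
    with open(path, "w") as fh:
        fh.write(f"# p_adj={p_adj}\tp_prun={p_prun}\tR={schedule.R}\n")
        fh.write("round\tthreshold\n")
        for r, c in enumerate(schedule.thresholds, start=1):
            fh.write(f"{r}\t{c}\n")


def read_schedule(path) -> PruningSchedule:
    """Read back a schedule written by :func:`write_schedule` (lossless)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ScheduleError("schedule file is missing its parameter header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("# ").split("\t")
        )
        colnames = fh.readline().strip().split("\t")
        if colnames != ["round", "threshold"]:
            raise ScheduleError(f"unexpected schedule columns: {colnames}")
        rounds, thresholds = [], []
        for line in fh:
            r_s, c_s = line.split("\t")
            rounds.append(int(r_s))
            thresholds.append(int(c_s))
    R = int(fields["R"])
    if rounds != list(range(1, R + 1)):
        raise ScheduleError("schedule file rounds are not 1..R")
    if fields["p_adj"] == "NA":
        params = None
    else:
        params = SignificanceParams(
            p_adj=float(fields["p_adj"]), p_prun=float(fields["p_prun"])
        )
    return PruningSchedule(params=params, R=R, thresholds=np.array(thresholds))
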