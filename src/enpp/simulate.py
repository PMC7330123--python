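"""Null-feature simulation of the pruning process and its efficiency curves.

Non-associated features are simulated at the exceedance level: each feature
draws a latent true permutation p-value from Uniform(0, 1) and its per-round
exceedances are Bernoulli with that probability.  Two equivalent simulators
are provided — a literal round-by-round Bernoulli walk and a fast path that
draws geometric waiting times between exceedances, whose cost per feature is
bounded by the schedule's maximum threshold and does not grow with the
number of rounds.

Deterministic expected curves come from quadrature over the latent p
combined with dynamic programming over exceedance-count states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .schedule import PruningSchedule, ScheduleError, SignificanceParams, build_schedule

__all__ = [
    "SimulationResult",
    "IceCurve",
    "Type1Result",
    "simulate_null_features",
    "expected_remaining",
    "expected_ice",
    "ice_curve",
    "type1_experiment",
    "expected_type1_rate",
    "expected_false_positive_count",
]


@dataclass
class SimulationResult:
    """Per-round survivor counts and cumulative test counts for one run."""

    schedule: PruningSchedule
    n_features: int
    remaining: np.ndarray  # remaining[r-1]: features not yet pruned after round r
    cumulative_tests: np.ndarray  # cumulative_tests[r-1]: total feature-tests through round r
    seed: Optional[int] = None
    method: str = "geometric"
    n_draws: int = 0

    def __post_init__(self) -> None:
        self.remaining = np.asarray(self.remaining, dtype=np.int64)
        self.cumulative_tests = np.asarray(self.cumulative_tests, dtype=np.int64)
        R = self.schedule.R
        if self.remaining.shape != (R,) or self.cumulative_tests.shape != (R,):
            raise ValueError("per-round arrays must have length R")
        if np.any(np.diff(self.remaining) > 0):
            raise ValueError("remaining counts must be non-increasing")
        if self.remaining[0] > self.n_features:
            raise ValueError("remaining cannot exceed the number of features")
        if np.any(np.diff(self.cumulative_tests) < 0):
            raise ValueError("cumulative test counts must be non-decreasing")

    @property
    def remaining_fraction(self) -> np.ndarray:
        return self.remaining / self.n_features

    def to_frame(self) -> pd.DataFrame:
        R = self.schedule.R
        return pd.DataFrame(
            {
                "round": np.arange(1, R + 1),
                "remaining": self.remaining,
                "cumulative_tests": self.cumulative_tests,
                "ice": ice_curve(self).values,
            }
        )


ICE_CONVENTIONS = ("entering", "completed")


@dataclass
class IceCurve:
    """Inverse computational efficiency per round.

    Under the default ``entering`` convention,
    ``values[r-1] = cumulative_tests[r] / (n_features * r)``: the fraction of
    the work an unpruned permutation test would have done by round r, where
    every round a feature entered (including the round it was pruned in)
    counts as one test.  The ``completed`` convention instead accumulates the
    survivor count after each round, i.e. it does not bill a feature for the
    round in which it was pruned; over many rounds the two differ by roughly
    one full pass over the features.
    """

    values: np.ndarray
    convention: str = "entering"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.convention not in ICE_CONVENTIONS:
            raise ValueError(f"convention must be one of {ICE_CONVENTIONS}")
        if np.any(self.values < 0) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("ICE values must lie in [0, 1]")


def ice_curve(sim: SimulationResult, convention: str = "entering") -> IceCurve:
    r = np.arange(1, sim.schedule.R + 1)
    if convention == "entering":
        cum = sim.cumulative_tests
    elif convention == "completed":
        cum = np.cumsum(sim.remaining)
    else:
        raise ValueError(f"convention must be one of {ICE_CONVENTIONS}")
    return IceCurve(values=cum / (sim.n_features * r), convention=convention)


def _prune_geometric(
    p: np.ndarray, thresholds: np.ndarray, R: int, rng: np.random.Generator
) -> Tuple[np.ndarray, int]:
    """Pruning rounds (0 = survived) for latent exceedance probabilities ``p``.

    Draws only the geometric waiting times between exceedances.  A feature's
    count is a step function that rises at exceedance rounds, and thresholds
    never decrease, so a feature can only be pruned at an exceedance round;
    the walk therefore needs at most ``max(thresholds)`` draws per feature.
    """
    n = p.size
    pruned_round = np.zeros(n, dtype=np.int64)
    ids = np.arange(n)
    t = np.zeros(n, dtype=np.int64)
    act_p = p
    n_draws = 0
    j = 0
    while ids.size:
        j += 1
        gaps = rng.geometric(act_p)
        n_draws += ids.size
        t = t + gaps
        inside = t <= R
        ids, t, act_p = ids[inside], t[inside], act_p[inside]  # others survive
        if ids.size == 0:
            break
        hit = j >= thresholds[t - 1]
        pruned_round[ids[hit]] = t[hit]
        keep = ~hit
        ids, t, act_p = ids[keep], t[keep], act_p[keep]
    return pruned_round, n_draws


def _prune_per_round(
    p: np.ndarray, thresholds: np.ndarray, R: int, rng: np.random.Generator
) -> Tuple[np.ndarray, int]:
    """Literal round-by-round Bernoulli simulation (reference path)."""
    n = p.size
    pruned_round = np.zeros(n, dtype=np.int64)
    ids = np.arange(n)
    counts = np.zeros(n, dtype=np.int64)
    act_p = p
    n_draws = 0
    for r in range(1, R + 1):
        if ids.size == 0:
            break
        counts = counts + (rng.random(ids.size) < act_p)
        n_draws += ids.size
        hit = counts >= thresholds[r - 1]
        pruned_round[ids[hit]] = r
        keep = ~hit
        ids, counts, act_p = ids[keep], counts[keep], act_p[keep]
    return pruned_round, n_draws


def _curves_from_pruned_rounds(
    pruned_round: np.ndarray, n: int, R: int
) -> Tuple[np.ndarray, np.ndarray]:
    pruned_at = np.bincount(pruned_round[pruned_round > 0], minlength=R + 1)[1:]
    pruned_cum = np.cumsum(pruned_at)
    remaining = n - pruned_cum
    entering = np.empty(R, dtype=np.int64)
    entering[0] = n
    entering[1:] = remaining[:-1]
    return remaining, np.cumsum(entering)


def simulate_null_features(
    n: int,
    schedule: PruningSchedule,
    seed: Optional[int] = None,
    method: str = "geometric",
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Simulate ``n`` independent null features against a schedule.

    Each feature draws a latent true p ~ Uniform(0, 1); exceedances are
    Bernoulli(p) per round.  ``method="per_round"`` draws them literally;
    ``method="geometric"`` draws waiting times between exceedances and is
    distributionally identical at O(max threshold) draws per feature.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    if method == "geometric":
        pruned_round, n_draws = _prune_geometric(p, schedule.thresholds, schedule.R, rng)
    elif method == "per_round":
        pruned_round, n_draws = _prune_per_round(p, schedule.thresholds, schedule.R, rng)
    else:
        raise ValueError(f"method must be 'geometric' or 'per_round', got {method!r}")
    remaining, cumulative = _curves_from_pruned_rounds(pruned_round, n, schedule.R)
    return SimulationResult(
        schedule=schedule,
        n_features=n,
        remaining=remaining,
        cumulative_tests=cumulative,
        seed=seed,
        method=method,
        n_draws=n_draws,
    )


def expected_remaining(
    schedule: PruningSchedule, grid_size: int = 256, transform_power: int = 4
) -> np.ndarray:
    """Expected fraction of null features still unpruned after each round.

    Integrates, over p ~ Uniform(0, 1) on a Gauss–Legendre grid, the exact
    survival probability of the exceedance-count process against the
    schedule (dynamic programming over count states).  The substitution
    ``p = u ** transform_power`` concentrates nodes near p = 0, where the
    long-run survivors live (the boundary layer has width ~ 1/R); the
    integrand stays polynomial in u, so early rounds remain exact to
    machine precision.
    """
    if grid_size < 64:
        raise ValueError(f"grid_size must be >= 64, got {grid_size}")
    if transform_power < 1:
        raise ValueError("transform_power must be >= 1")
    t = schedule.thresholds
    K = int(t.max())
    if K > 10_000:
        raise ScheduleError("schedule thresholds too large for the survival DP")
    u, wu = np.polynomial.legendre.leggauss(grid_size)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    m = transform_power
    x = u**m
    w = wu * m * u ** (m - 1)
    # state[i, k]: P(alive with count == k | p = x[i]); counts above K-1 are
    # necessarily at/above the current threshold and are absorbed on creation
    state = np.zeros((grid_size, K))
    state[:, 0] = 1.0
    xm = x[:, None]
    out = np.empty(schedule.R)
    for r in range(1, schedule.R + 1):
        new = state * (1.0 - xm)
        new[:, 1:] += state[:, :-1] * xm
        c = t[r - 1]
        if c <= K:
            new[:, c:] = 0.0
        state = new
        out[r - 1] = w @ state.sum(axis=1)
    return out


def expected_ice(
    schedule: PruningSchedule, grid_size: int = 256, convention: str = "entering"
) -> Tuple[np.ndarray, IceCurve]:
    """Expected remaining fractions and the ICE curve they imply."""
    rem = expected_remaining(schedule, grid_size=grid_size)
    if convention == "entering":
        entering = np.empty(schedule.R)
        entering[0] = 1.0
        entering[1:] = rem[:-1]
        cum = np.cumsum(entering)
    elif convention == "completed":
        cum = np.cumsum(rem)
    else:
        raise ValueError(f"convention must be one of {ICE_CONVENTIONS}")
    ice = IceCurve(values=cum / np.arange(1, schedule.R + 1), convention=convention)
    return rem, ice


def expected_false_positive_count(n_features: int, p_adj: float, follow_up_R: int) -> float:
    """Expected count of null features whose follow-up permutation p-value
    lands at or below ``p_adj`` (ignoring pruning; latent p uniform).

    With p-value (1 + k) / (R + 1), significance requires
    k <= p_adj * (R + 1) - 1, and integrating the binomial CDF over uniform
    p gives exactly (m + 1) / (R + 1) per feature.
    """
    m = int(np.floor(p_adj * (follow_up_R + 1) - 1 + 1e-12))
    if m < 0:
        return 0.0
    return n_features * (m + 1) / (follow_up_R + 1)


def expected_type1_rate(
    params: SignificanceParams,
    R: int,
    follow_up_R: int,
    grid_size: int = 256,
    transform_power: int = 4,
) -> float:
    """Exact expected family-wise type-I rate of pruning plus follow-up.

    Integrates P(survive pruning | p) * P(follow-up p-value <= p_adj | p)
    over the latent p ~ Uniform(0, 1), scaled to one ``p_raw / p_adj``-sized
    family.  Slightly below nominal: the deficit is the (small) probability
    that a feature extreme enough to reach significance was pruned first.
    """
    from scipy.stats import binom as _binom

    schedule = build_schedule(params, R)
    t = schedule.thresholds
    K = int(t.max())
    u, wu = np.polynomial.legendre.leggauss(grid_size)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    m = transform_power
    x = u**m
    w = wu * m * u ** (m - 1)
    state = np.zeros((grid_size, K))
    state[:, 0] = 1.0
    xm = x[:, None]
    for r in range(1, R + 1):
        new = state * (1.0 - xm)
        new[:, 1:] += state[:, :-1] * xm
        c = t[r - 1]
        if c <= K:
            new[:, c:] = 0.0
        state = new
    survive = state.sum(axis=1)
    m_sig = int(np.floor(params.p_adj * (follow_up_R + 1) - 1 + 1e-12))
    if m_sig < 0:
        return 0.0
    sig = _binom.cdf(m_sig, follow_up_R, x)
    p_raw = params.p_raw if params.p_raw is not None else 0.05
    family_size = p_raw / params.p_adj
    return float(family_size * (w @ (survive * sig)))


@dataclass
class Type1Result:
    """Family-wise type-I error estimate with a confidence interval."""

    rate: float
    se: float
    ci_low: float
    ci_high: float
    replicate_rates: np.ndarray
    family_count: float
    expected_false_positives: float
    metadata: dict = field(default_factory=dict)


def type1_experiment(
    n_features: int,
    params: SignificanceParams,
    R: int,
    follow_up_R: int,
    replicates: int = 1,
    seed: Optional[int] = None,
    ci: str = "normal",
) -> Type1Result:
    """Estimate the family-wise type-I error of pruning plus follow-up.

    Null features (latent p ~ Uniform) are pruned against the schedule;
    survivors get a follow-up permutation of ``follow_up_R`` rounds (their
    exceedance counts are Binomial draws at the latent p, the two stages
    being independent).  A feature is a false positive when its follow-up
    p-value is at or below ``p_adj``.  The false-positive count is divided
    by the number of ``p_raw / p_adj``-sized families the feature pool
    represents, and replicate rates are averaged.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    p_raw = params.p_raw if params.p_raw is not None else 0.05
    family_size = p_raw / params.p_adj
    family_count = n_features / family_size
    schedule = build_schedule(params, R)
    thresholds = schedule.thresholds
    p_adj = params.p_adj
    rates = np.empty(replicates)
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        p = rng.uniform(size=n_features)
        pruned_round, _ = _prune_geometric(p, thresholds, R, rng)
        p_surv = p[pruned_round == 0]
        k = rng.binomial(follow_up_R, p_surv)
        pvals = (1.0 + k) / (follow_up_R + 1.0)
        rates[i] = (pvals <= p_adj).sum() / family_count
    rate = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else float("nan")
    if ci == "normal" or replicates == 1:
        half = 1.959963984540054 * se
        ci_low, ci_high = rate - half, rate + half
    elif ci == "clopper-pearson":
        from scipy.stats import beta

        # treat mean rate as a proportion of family_count * replicates trials
        trials = int(round(family_count * replicates))
        successes = int(round(rate * trials))
        ci_low = float(beta.ppf(0.025, successes, trials - successes + 1)) if successes else 0.0
        ci_high = float(beta.ppf(0.975, successes + 1, trials - successes))
    else:
        raise ValueError("ci must be 'normal' or 'clopper-pearson'")
    return Type1Result(
        rate=rate,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        replicate_rates=rates,
        family_count=family_count,
        expected_false_positives=expected_false_positive_count(
            n_features, p_adj, follow_up_R
        ),
        metadata={
            "n_features": n_features,
            "R": R,
            "follow_up_R": follow_up_R,
            "replicates": replicates,
            "p_adj": p_adj,
            "p_raw": p_raw,
            "seed": seed,
        },
    )
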