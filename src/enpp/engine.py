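"""The pruning permutation engine.

One shared random permutation of the phenotype is drawn per round and the
statistic is recomputed for every still-active feature.  A feature whose
cumulative exceedance count reaches the schedule threshold at the end of a
round is pruned from all later rounds.  Survivors of the final round get a
standard Monte-Carlo permutation p-value; pruned features get only a lower
bound, because their counts form a stopped sequence.

Per-round randomness comes from a counter-based generator keyed on
``(seed, round)``, so the permutation used in round ``r`` does not depend on
pruning history.  This makes the procedure trivially parallelizable by
round and makes "pruning never changes a survivor's p-value" an exact,
testable identity rather than a distributional statement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .schedule import PruningSchedule
from .stats import StatisticSpec, exact_binom_compare, exceeds, get_statistic

__all__ = [
    "DatasetBundle",
    "FeatureState",
    "ResultTable",
    "run_enpp",
    "full_permutation",
    "compare_with_parametric",
    "RESULT_COLUMNS",
]

logger = logging.getLogger("enpp.engine")

RESULT_COLUMNS = [
    "feature_id",
    "s_obs",
    "exceed_count",
    "rounds_tested",
    "status",
    "pruned_round",
    "p_value",
    "p_lower_bound",
]


class EngineError(ValueError):
    pass


@dataclass
class DatasetBundle:
    """Aligned feature matrix, phenotype, covariates and missingness mask."""

    features: np.ndarray  # N x J
    phenotype: np.ndarray  # N
    covariates: Optional[np.ndarray]  # N x q or None
    missing_mask: Optional[np.ndarray] = None  # N x J boolean
    feature_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise EngineError("features must be an N x J matrix")
        N, J = self.features.shape
        self.phenotype = np.asarray(self.phenotype, dtype=float).ravel()
        if self.phenotype.size != N:
            raise EngineError("phenotype length does not match feature rows")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != N:
                raise EngineError("covariate rows do not match feature rows")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.features)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (N, J):
                raise EngineError("missing_mask shape does not match features")
        if self.feature_ids is None:
            width = len(str(J))
            self.feature_ids = [f"feat{i:0{width}d}" for i in range(1, J + 1)]
        else:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != J:
                raise EngineError("feature_ids length does not match J")
            if len(set(self.feature_ids)) != J:
                raise EngineError("feature_ids must be unique")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != N:
                raise EngineError("sample_ids length does not match N")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def select(self, feature_ids: Sequence[str]) -> "DatasetBundle":
        """Sub-bundle restricted to the given features, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise EngineError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return DatasetBundle(
            features=self.features[:, cols],
            phenotype=self.phenotype,
            covariates=self.covariates,
            missing_mask=self.missing_mask[:, cols],
            feature_ids=list(feature_ids),
            sample_ids=self.sample_ids,
            metadata=dict(self.metadata),
        )


@dataclass
class FeatureState:
    """Running permutation bookkeeping for a single feature."""

    feature_id: str
    s_obs: float
    exceed_count: int = 0
    rounds_tested: int = 0
    status: str = "active"
    pruned_round: Optional[int] = None


@dataclass
class ResultTable:
    """Per-feature outcomes plus run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise EngineError(f"result table missing columns: {missing}")

    @property
    def survivors(self) -> list:
        mask = self.table["status"] == "completed"
        return list(self.table.loc[mask, "feature_id"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}={self.metadata[key]}\n")
            self.table.to_csv(fh, sep="\t", index=False, columns=RESULT_COLUMNS)

    @classmethod
    def from_tsv(cls, path) -> "ResultTable":
        metadata = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
                metadata[key] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t", dtype={"feature_id": str})
        return cls(table=table, metadata=metadata)


def _round_rng(seed: int, r: int) -> np.random.Generator:
    # counter-based: round r's permutation is independent of pruning history
    return np.random.Generator(np.random.Philox(key=seed).jumped(r))


def _checkpoints(R: int) -> set:
    if R <= 1000:
        return set(range(1, R + 1))
    pts = {1, R}
    v = 1
    while v < R:
        for m in (1, 2, 5):
            if v * m <= R:
                pts.add(v * m)
        v *= 10
    return pts


def _run_permutations(
    data: DatasetBundle,
    schedule: PruningSchedule,
    stat: StatisticSpec,
    seed: int,
    include_observed: bool,
) -> ResultTable:
    model_cls = get_statistic(stat.name)
    model = model_cls(
        data.features,
        data.phenotype,
        covariates=data.covariates,
        missing_mask=data.missing_mask,
    )
    J = data.n_features
    R = schedule.R
    s_obs = model.observed()
    valid = model.valid & np.isfinite(s_obs)
    n_failed = int(J - valid.sum())
    if n_failed:
        logger.info("excluding %d feature(s) with undefined statistic", n_failed)

    counts = np.zeros(J, dtype=np.int64)
    rounds_tested = np.zeros(J, dtype=np.int64)
    pruned_round = np.zeros(J, dtype=np.int64)  # 0 = never pruned
    active = valid.copy()
    thresholds = schedule.thresholds
    y = data.phenotype
    N = data.n_samples
    checkpoints = _checkpoints(R)

    for r in range(1, R + 1):
        cols = np.flatnonzero(active)
        if cols.size == 0:
            break
        rng = _round_rng(seed, r)
        y_perm = y[rng.permutation(N)]
        s_perm = model.evaluate(y_perm, cols=cols)
        counts[cols] += exceeds(s_obs[cols], s_perm, stat.alternative)
        rounds_tested[cols] += 1
        hit = counts[cols] >= thresholds[r - 1]
        if hit.any():
            pruned = cols[hit]
            pruned_round[pruned] = r
            active[pruned] = False
        if r in checkpoints:
            total = int(rounds_tested.sum())
            logger.info(
                "round %d: active=%d cumulative_tests=%d ice=%.4g",
                r,
                int(active.sum()),
                total,
                total / (max(int(valid.sum()), 1) * r),
            )

    status = np.where(valid, np.where(pruned_round > 0, "pruned", "completed"), "failed")
    p_value = np.full(J, np.nan)
    p_lower = np.full(J, np.nan)
    completed = status == "completed"
    if include_observed:
        p_value[completed] = (1.0 + counts[completed]) / (R + 1.0)
    else:
        p_value[completed] = counts[completed] / R
    pruned_mask = status == "pruned"
    p_lower[pruned_mask] = counts[pruned_mask] / rounds_tested[pruned_mask]

    table = pd.DataFrame(
        {
            "feature_id": data.feature_ids,
            "s_obs": s_obs,
            "exceed_count": counts,
            "rounds_tested": rounds_tested,
            "status": status,
            "pruned_round": np.where(pruned_round > 0, pruned_round, -1),
            "p_value": p_value,
            "p_lower_bound": p_lower,
        }
    )
    metadata = {
        "seed": seed,
        "R": R,
        "statistic": stat.name,
        "alternative": stat.alternative,
        "include_observed": include_observed,
        "total_tests_performed": int(rounds_tested.sum()),
        "n_features": J,
        "n_failed": n_failed,
    }
    if schedule.params is not None:
        metadata["p_adj"] = schedule.params.p_adj
        metadata["p_prun"] = schedule.params.p_prun
    return ResultTable(table=table, metadata=metadata)


def run_enpp(
    data: DatasetBundle,
    schedule: PruningSchedule,
    stat: Optional[StatisticSpec] = None,
    seed: int = 0,
    include_observed: bool = True,
) -> ResultTable:
    """Run the pruning permutation procedure.

    Observed statistics are computed once on unpermuted data; then, for each
    round, one shared phenotype permutation is drawn, the statistic is
    re-evaluated for all active features, exceedance counts accumulate, and
    features whose count reaches the round's threshold are pruned.
    Identical seeds yield bit-identical results.
    """
    if stat is None:
        stat = StatisticSpec()
    if data.n_features < 1:
        raise EngineError("dataset has no features")
    return _run_permutations(data, schedule, stat, seed, include_observed)


def full_permutation(
    data: DatasetBundle,
    feature_ids: Optional[Sequence[str]],
    R_full: int,
    stat: Optional[StatisticSpec] = None,
    seed: int = 0,
    include_observed: bool = True,
) -> ResultTable:
    """Plain unpruned permutation test on a subset of features.

    Uses the same round-indexed seeding policy as :func:`run_enpp`, so with
    equal seeds and equal round counts a survivor's p-value here matches its
    pruning-run p-value exactly.
    """
    if stat is None:
        stat = StatisticSpec()
    if feature_ids is not None:
        feature_ids = list(feature_ids)
        if not feature_ids:
            table = pd.DataFrame({c: [] for c in RESULT_COLUMNS})
            return ResultTable(
                table=table,
                metadata={"seed": seed, "R": R_full, "statistic": stat.name,
                          "alternative": stat.alternative,
                          "include_observed": include_observed,
                          "total_tests_performed": 0, "n_features": 0,
                          "n_failed": 0},
            )
        data = data.select(feature_ids)
    return _run_permutations(
        data, PruningSchedule.no_pruning(R_full), stat, seed, include_observed
    )


def compare_with_parametric(
    result: ResultTable,
    parametric_pvalues: Union[Mapping[str, float], pd.Series],
) -> pd.DataFrame:
    """Exact binomial comparison of permutation counts against parametric p-values.

    For each completed feature, tests H0: exceedance probability equals the
    parametric p-value.  Pruned or failed features are marked not comparable.
    """
    if isinstance(parametric_pvalues, pd.Series):
        parametric_pvalues = parametric_pvalues.to_dict()
    records = []
    for row in result.table.itertuples(index=False):
        fid = row.feature_id
        if fid not in parametric_pvalues:
            raise EngineError(f"no parametric p-value for feature {fid!r}")
        p0 = float(parametric_pvalues[fid])
        comparable = row.status == "completed"
        cmp_p = (
            exact_binom_compare(int(row.exceed_count), int(row.rounds_tested), p0)
            if comparable
            else np.nan
        )
        records.append(
            {
                "feature_id": fid,
                "exceed_count": row.exceed_count,
                "rounds_tested": row.rounds_tested,
                "parametric_p": p0,
                "comparable": comparable,
                "comparison_p": cmp_p,
            }
        )
    return pd.DataFrame.from_records(records)
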