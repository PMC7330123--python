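"""Test statistics and p-value machinery for the permutation engine.

The default statistic is the t-statistic of the genotype term in a linear
model ``y ~ intercept + covariates + g`` with additively coded genotype
(minor-allele dosage 0/1/2).  It is computed by residualizing both the
phenotype and the genotype on the covariate design and running the simple
regression of the residuals with ``N - q - 2`` degrees of freedom, which
equals the full-design t exactly and lets the engine evaluate all features
against one permuted phenotype with a single matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "StatisticError",
    "ConstantFeatureError",
    "DesignError",
    "StatisticSpec",
    "PValueRecord",
    "exceeds",
    "permutation_pvalue",
    "exact_binom_compare",
    "lm_additive_t",
    "LinearModelT",
    "get_statistic",
    "STATISTICS",
]

ALTERNATIVES = ("two-sided", "greater", "less")

_RANK_TOL = 1e-10


class StatisticError(ValueError):
    """A statistic could not be computed."""


class ConstantFeatureError(StatisticError):
    """The feature has no variation after missing-data handling."""


class DesignError(StatisticError):
    """The covariate design is rank deficient or too large for N."""


@dataclass(frozen=True)
class PValueRecord:
    """Permutation p-value bookkeeping for one feature."""

    exceed_count: int
    rounds: int
    include_observed: bool = True

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise StatisticError(f"rounds must be >= 1, got {self.rounds}")
        if not 0 <= self.exceed_count <= self.rounds:
            raise StatisticError(
                f"need 0 <= exceed_count <= rounds, got "
                f"{self.exceed_count} / {self.rounds}"
            )

    @property
    def p_value(self) -> float:
        return permutation_pvalue(
            self.exceed_count, self.rounds, include_observed=self.include_observed
        )


def exceeds(
    s_obs: Union[float, np.ndarray],
    s_perm: Union[float, np.ndarray],
    alternative: str = "two-sided",
):
    """Indicator that the permuted statistic is at least as extreme as the
    observed one.  Ties count as exceedances (non-strict inequality).

    Works elementwise on arrays; returns int or an integer array.
    """
    if alternative == "two-sided":
        out = np.abs(s_perm) >= np.abs(s_obs)
    elif alternative == "greater":
        out = np.asarray(s_perm) >= s_obs
    elif alternative == "less":
        out = np.asarray(s_perm) <= s_obs
    else:
        raise StatisticError(f"alternative must be one of {ALTERNATIVES}")
    out = np.asarray(out, dtype=np.int64)
    return int(out) if out.ndim == 0 else out


def permutation_pvalue(
    exceed_count: int, rounds: int, include_observed: bool = True
) -> float:
    """Monte-Carlo permutation p-value from an exceedance count.

    ``(1 + count) / (rounds + 1)`` by default; the +1 terms (which place the
    observed statistic in its own null distribution) can be omitted.
    """
    if rounds < 1:
        raise StatisticError(f"rounds must be >= 1, got {rounds}")
    if not 0 <= exceed_count <= rounds:
        raise StatisticError(
            f"need 0 <= exceed_count <= rounds, got {exceed_count} / {rounds}"
        )
    if include_observed:
        return (1 + exceed_count) / (rounds + 1)
    return exceed_count / rounds


def exact_binom_compare(exceed_count: int, rounds: int, p0: float) -> float:
    """Two-sided exact binomial test of H0: exceedance probability = p0.

    Used to compare a permutation result (``exceed_count`` exceedances in
    ``rounds`` trials) against a parametric p-value ``p0`` treated as the
    null success probability.  Minimum-likelihood two-sided convention.
    """
    if not 0.0 < p0 < 1.0:
        raise StatisticError(f"p0 must be in (0, 1), got {p0}")
    if rounds < 1 or not 0 <= exceed_count <= rounds:
        raise StatisticError(
            f"need 0 <= exceed_count <= rounds, got {exceed_count} / {rounds}"
        )
    return float(binomtest(exceed_count, rounds, p0, alternative="two-sided").pvalue)


def _covariate_design(N: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    if covariates is None:
        X0 = np.ones((N, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != N:
            covariates = covariates.T
        if covariates.shape[0] != N:
            raise DesignError("covariate matrix does not match phenotype length")
        X0 = np.column_stack([np.ones(N), covariates])
    return X0


def _orthonormal_basis(X0: np.ndarray) -> np.ndarray:
    Q, Rm = np.linalg.qr(X0)
    diag = np.abs(np.diag(Rm))
    if np.any(diag <= _RANK_TOL * max(1.0, diag.max())):
        raise DesignError("covariate design (with intercept) is rank deficient")
    return Q


def lm_additive_t(
    y: np.ndarray, g: np.ndarray, covariates: Optional[np.ndarray] = None
) -> float:
    """t-statistic for the genotype term of ``y ~ 1 + covariates + g``.

    Residualizes ``y`` and ``g`` on the intercept-plus-covariate design and
    regresses the residuals, with ``N - q - 2`` degrees of freedom so the
    result equals the full-design least-squares t.  A perfectly fitting
    genotype (zero residual variance) returns signed infinity.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    N = y.size
    if g.size != N:
        raise StatisticError("y and g must have the same length")
    X0 = _covariate_design(N, covariates)
    q = X0.shape[1] - 1
    if N <= q + 2:
        raise DesignError(f"need N > q + 2, got N={N}, q={q}")
    Q = _orthonormal_basis(X0)
    g_res = g - Q @ (Q.T @ g)
    y_res = y - Q @ (Q.T @ y)
    gss = float(g_res @ g_res)
    if gss <= _RANK_TOL * max(1.0, float(g @ g)):
        raise ConstantFeatureError(
            "genotype is constant (or collinear with covariates)"
        )
    num = float(g_res @ y_res)
    rss = float(y_res @ y_res) - num * num / gss
    df = N - q - 2
    if rss <= _RANK_TOL * max(1.0, float(y_res @ y_res)):
        return math_inf_signed(num)
    return num / np.sqrt(gss * rss / df)


def math_inf_signed(x: float) -> float:
    return float(np.inf) if x >= 0 else float(-np.inf)


class LinearModelT:
    """Batch evaluator for :func:`lm_additive_t` over a feature matrix.

    Precomputes the covariate basis and residualized (mean-imputed) feature
    matrix once; each permutation round then costs one matrix-vector
    product.  Features that are constant after imputation are marked
    invalid and evaluate to NaN.
    """

    name = "lm_additive_t"

    def __init__(
        self,
        features: np.ndarray,
        phenotype: np.ndarray,
        covariates: Optional[np.ndarray] = None,
        missing_mask: Optional[np.ndarray] = None,
    ) -> None:
        y = np.asarray(phenotype, dtype=float).ravel()
        G = np.array(features, dtype=float)
        N, J = G.shape
        if y.size != N:
            raise StatisticError("phenotype length does not match feature rows")
        X0 = _covariate_design(N, covariates)
        q = X0.shape[1] - 1
        if N <= q + 2:
            raise DesignError(f"need N > q + 2, got N={N}, q={q}")
        if missing_mask is None:
            missing_mask = ~np.isfinite(G)
        else:
            missing_mask = np.asarray(missing_mask, dtype=bool) | ~np.isfinite(G)
        if missing_mask.any():
            G = G.copy()
            G[missing_mask] = np.nan
            col_mean = np.nanmean(np.where(missing_mask, np.nan, G), axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            fill = np.broadcast_to(col_mean, G.shape)
            G[missing_mask] = fill[missing_mask]
        self.Q = _orthonormal_basis(X0)
        self.df = N - q - 2
        self.G_res = G - self.Q @ (self.Q.T @ G)
        self.gss = np.einsum("ij,ij->j", self.G_res, self.G_res)
        scale = np.maximum(1.0, np.einsum("ij,ij->j", G, G))
        self.valid = self.gss > _RANK_TOL * scale
        self.y = y

    @property
    def n_features(self) -> int:
        return self.G_res.shape[1]

    def evaluate(self, y: np.ndarray, cols: Optional[np.ndarray] = None) -> np.ndarray:
        """t-statistics for ``y`` against every (or the selected) feature."""
        y_res = y - self.Q @ (self.Q.T @ y)
        yss = float(y_res @ y_res)
        G_res = self.G_res if cols is None else self.G_res[:, cols]
        gss = self.gss if cols is None else self.gss[cols]
        valid = self.valid if cols is None else self.valid[cols]
        num = G_res.T @ y_res
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = np.maximum(yss - num * num / gss, 0.0)
            t = num / np.sqrt(gss * rss / self.df)
            t = np.where(np.isnan(t) & (np.abs(num) > 0), np.sign(num) * np.inf, t)
        t[~valid] = np.nan
        return t

    def observed(self, cols: Optional[np.ndarray] = None) -> np.ndarray:
        return self.evaluate(self.y, cols=cols)


STATISTICS = {LinearModelT.name: LinearModelT}


def get_statistic(name: str):
    """Resolve a registered batch statistic implementation by name."""
    try:
        return STATISTICS[name]
    except KeyError:
        raise StatisticError(
            f"unknown statistic {name!r}; registered: {sorted(STATISTICS)}"
        ) from None


@dataclass(frozen=True)
class StatisticSpec:
    """Named statistic plus sidedness, resolvable from CLI or config."""

    name: str = "lm_additive_t"
    alternative: str = "two-sided"
    handles_covariates: bool = True

    def __post_init__(self) -> None:
        get_statistic(self.name)
        if self.alternative not in ALTERNATIVES:
            raise StatisticError(
                f"alternative must be one of {ALTERNATIVES}, got {self.alternative!r}"
            )
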