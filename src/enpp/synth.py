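"""Synthetic GWAS-like datasets: additive SNP effects, a strongly
right-skewed quantitative phenotype, and age/sex/region covariates.

Stands in for restricted cohort data in every test and example.  Genotypes
are Binomial(2, MAF) dosages with MAF drawn uniformly from a configurable
range; the phenotype is a covariate signal plus optional additive causal
effects plus standardized noise from a skewed family whose shape parameter
is solved numerically from the requested skewness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import skew as _scipy_skew

from .engine import DatasetBundle

__all__ = [
    "SynthConfigError",
    "CovariateSpec",
    "SynthConfig",
    "generate_dataset",
    "sample_skewness",
    "log_sample_skewness",
    "lognormal_sigma_for_skewness",
]

PHENOTYPE_FAMILIES = ("skewed_lognormal", "skewed_chisq", "gaussian")


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateSpec:
    """Age/sex/region-like covariate columns and their phenotype slopes.

    Region is binary (two cohorts); sex is binary; age is uniform on an
    adult range.  Units are arbitrary — the structure is what matters.
    """

    age_range: Tuple[float, float] = (40.0, 70.0)
    age_effect: float = 0.05
    sex_effect: float = 0.5
    region_effect: float = 0.3


@dataclass(frozen=True)
class SynthConfig:
    N: int
    J: int
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_causal: int = 0
    effect_sizes: Union[float, Sequence[float], None] = None
    phenotype_family: str = "skewed_lognormal"
    target_skewness: float = 5.32
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    missing_rate: float = 0.0
    baseline: float = 80.0
    noise_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 3 or self.J < 1:
            raise SynthConfigError("need N >= 3 and J >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SynthConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.n_causal <= self.J:
            raise SynthConfigError("need 0 <= n_causal <= J")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SynthConfigError("missing_rate must be in [0, 1)")
        if self.phenotype_family not in PHENOTYPE_FAMILIES:
            raise SynthConfigError(
                f"phenotype_family must be one of {PHENOTYPE_FAMILIES}"
            )
        if self.phenotype_family != "gaussian" and self.target_skewness <= 0:
            raise SynthConfigError(
                "skewed phenotype families need target_skewness > 0"
            )


def lognormal_sigma_for_skewness(target: float) -> float:
    """Shape parameter sigma with lognormal skewness (w+2)sqrt(w-1), w = exp(sigma^2)."""
    if target <= 0:
        raise SynthConfigError("lognormal skewness must be positive")

    def f(sigma: float) -> float:
        w = np.exp(sigma**2)
        return (w + 2.0) * np.sqrt(w - 1.0) - target

    return brentq(f, 1e-8, 5.0)


def _standardized_noise(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero, unit-variance noise with the configured skewness."""
    N = config.N
    if config.phenotype_family == "gaussian":
        return rng.standard_normal(N)
    if config.phenotype_family == "skewed_lognormal":
        sigma = lognormal_sigma_for_skewness(config.target_skewness)
        raw = np.exp(sigma * rng.standard_normal(N))
        mean = np.exp(sigma**2 / 2.0)
        sd = np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2))
        return (raw - mean) / sd
    # chi-square skewness is sqrt(8 / df)
    df = 8.0 / config.target_skewness**2
    raw = rng.chisquare(df, size=N)
    return (raw - df) / np.sqrt(2.0 * df)


def generate_dataset(config: SynthConfig) -> DatasetBundle:
    """Draw a dataset; deterministic under the config's seed.

    Causal feature indices, per-feature MAFs, and the config are recorded in
    the bundle's metadata.
    """
    rng = np.random.default_rng(config.seed)
    N, J = config.N, config.J
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=J)
    G = rng.binomial(2, maf, size=(N, J)).astype(float)

    cs = config.covariate_spec
    age = rng.uniform(cs.age_range[0], cs.age_range[1], size=N)
    sex = rng.integers(0, 2, size=N).astype(float)
    region = rng.integers(0, 2, size=N).astype(float)
    covariates = np.column_stack([age, sex, region])
    eta = (
        cs.age_effect * (age - age.mean())
        + cs.sex_effect * sex
        + cs.region_effect * region
    )

    causal = np.sort(rng.choice(J, size=config.n_causal, replace=False))
    if config.n_causal:
        if config.effect_sizes is None:
            effects = np.full(config.n_causal, 0.3)
        else:
            effects = np.broadcast_to(
                np.asarray(config.effect_sizes, dtype=float), (config.n_causal,)
            )
        eta = eta + G[:, causal] @ effects
    else:
        effects = np.empty(0)

    noise = _standardized_noise(config, rng)
    phenotype = config.baseline + eta + config.noise_scale * noise

    missing_mask = np.zeros((N, J), dtype=bool)
    if config.missing_rate > 0:
        missing_mask = rng.random((N, J)) < config.missing_rate
    G_masked = G.copy()
    G_masked[missing_mask] = np.nan

    width = max(6, len(str(J)))
    feature_ids = [f"snp{i:0{width}d}" for i in range(1, J + 1)]
    sample_ids = [f"S{i:06d}" for i in range(1, N + 1)]
    return DatasetBundle(
        features=G_masked,
        phenotype=phenotype,
        covariates=covariates,
        missing_mask=missing_mask,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        metadata={
            "causal_indices": causal.tolist(),
            "causal_ids": [feature_ids[i] for i in causal],
            "effect_sizes": np.asarray(effects).tolist(),
            "maf": maf.tolist(),
            "config": config,
            "covariate_names": ["age", "sex", "region"],
        },
    )


def sample_skewness(values: np.ndarray) -> float:
    """Third standardized moment (biased moment estimator)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(values) == 0:
        raise ValueError("skewness is undefined for a zero-variance sample")
    return float(_scipy_skew(values, bias=True))


def log_sample_skewness(values: np.ndarray) -> float:
    """Skewness after natural-log transform (values must be positive)."""
    values = np.asarray(values, dtype=float).ravel()
    if np.any(values <= 0):
        raise ValueError("log transform requires strictly positive values")
    return sample_skewness(np.log(values))
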