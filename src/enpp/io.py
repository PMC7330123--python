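"""File formats: PLINK .raw-style genotype tables, delimited dosage
matrices, phenotype/covariate tables, run configuration, and provenance
headers for output files.

Sample alignment across genotype/phenotype/covariate files is by id join
with a hard error on mismatch — never silent reordering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DatasetBundle

__all__ = [
    "ParseError",
    "IdMismatchError",
    "GenotypeTable",
    "read_genotypes",
    "read_plink_raw",
    "read_delimited_genotypes",
    "write_plink_raw",
    "write_delimited",
    "read_sample_table",
    "assemble_bundle",
    "RunConfig",
    "provenance_header",
]

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_DOSAGE_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


class ParseError(ValueError):
    pass


class IdMismatchError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Dosage matrix fragment read from disk."""

    sample_ids: list
    feature_ids: list
    dosages: np.ndarray  # N x J, NaN where missing
    missing_mask: np.ndarray  # N x J boolean
    phenotype: Optional[np.ndarray] = None  # from PLINK .raw PHENOTYPE column


def _parse_dosage(token: str, line_no: int, col_no: int, path) -> float:
    try:
        return _DOSAGE_TOKENS[token]
    except KeyError:
        raise ParseError(
            f"{path}: line {line_no}, column {col_no}: "
            f"invalid dosage token {token!r} (expected 0/1/2/NA)"
        ) from None


def _parse_dosage_block(
    rows: list, path, first_line: int, first_col: int
) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0]) if rows else 0))
    for i, row in enumerate(rows):
        for j, token in enumerate(row):
            out[i, j] = _parse_dosage(token, first_line + i, first_col + j, path)
    return out


def read_plink_raw(path) -> GenotypeTable:
    """Read a PLINK .raw-style table (FID IID PAT MAT SEX PHENOTYPE + SNPs)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split()
        if header[: len(PLINK_RAW_META)] != PLINK_RAW_META:
            raise ParseError(
                f"{path}: malformed header; expected it to start with "
                f"{' '.join(PLINK_RAW_META)}"
            )
        feature_ids = header[len(PLINK_RAW_META) :]
        sample_ids, phenos, rows = [], [], []
        for line_no, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            phenos.append(parts[5])
            rows.append(parts[len(PLINK_RAW_META) :])
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids")
    if len(set(feature_ids)) != len(feature_ids):
        raise ParseError(f"{path}: duplicate feature ids")
    dosages = _parse_dosage_block(rows, path, 2, len(PLINK_RAW_META) + 1)
    phenotype = np.array(
        [np.nan if p in ("NA", "-9") else float(p) for p in phenos]
    )
    return GenotypeTable(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        dosages=dosages,
        missing_mask=np.isnan(dosages),
        phenotype=phenotype,
    )


def read_delimited_genotypes(path, sep: str = "\t", id_col: str = "IID") -> GenotypeTable:
    """Read a delimited table: one id column, then one 0/1/2/NA column per feature."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if header[0] != id_col:
            raise ParseError(f"{path}: first column must be {id_col!r}, got {header[0]!r}")
        feature_ids = header[1:]
        sample_ids, rows = [], []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if parts == [""]:
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[0])
            rows.append(parts[1:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids")
    if len(set(feature_ids)) != len(feature_ids):
        raise ParseError(f"{path}: duplicate feature ids")
    dosages = _parse_dosage_block(rows, path, 2, 2)
    return GenotypeTable(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        dosages=dosages,
        missing_mask=np.isnan(dosages),
    )


def read_genotypes(path, format: str = "plink_raw") -> GenotypeTable:
    if format == "plink_raw":
        return read_plink_raw(path)
    if format == "delimited":
        return read_delimited_genotypes(path)
    raise ParseError(f"unknown genotype format {format!r}")


def _format_dosage(v: float) -> str:
    return "NA" if not np.isfinite(v) else str(int(round(v)))


def write_plink_raw(bundle: DatasetBundle, path) -> None:
    """Write a bundle's genotypes (plus phenotype) as a PLINK .raw-style table."""
    sample_ids = bundle.sample_ids or [f"S{i:06d}" for i in range(1, bundle.n_samples + 1)]
    G = np.where(bundle.missing_mask, np.nan, bundle.features)
    with open(path, "w") as fh:
        fh.write(" ".join(PLINK_RAW_META + list(bundle.feature_ids)) + "\n")
        for i in range(bundle.n_samples):
            meta = [sample_ids[i], sample_ids[i], "0", "0", "0",
                    repr(float(bundle.phenotype[i]))]
            row = [_format_dosage(v) for v in G[i]]
            fh.write(" ".join(meta + row) + "\n")


def write_delimited(bundle: DatasetBundle, genotype_path, phenotype_path,
                    covariate_path, sep: str = "\t") -> None:
    """Write genotypes, phenotype, and covariates as separate delimited tables."""
    sample_ids = bundle.sample_ids or [f"S{i:06d}" for i in range(1, bundle.n_samples + 1)]
    G = np.where(bundle.missing_mask, np.nan, bundle.features)
    with open(genotype_path, "w") as fh:
        fh.write(sep.join(["IID"] + list(bundle.feature_ids)) + "\n")
        for i in range(bundle.n_samples):
            fh.write(sep.join([sample_ids[i]] + [_format_dosage(v) for v in G[i]]) + "\n")
    pd.DataFrame({"IID": sample_ids, "PHENOTYPE": bundle.phenotype}).to_csv(
        phenotype_path, sep=sep, index=False
    )
    names = bundle.metadata.get("covariate_names")
    q = 0 if bundle.covariates is None else bundle.covariates.shape[1]
    if names is None or len(names) != q:
        names = [f"cov{j + 1}" for j in range(q)]
    cov = pd.DataFrame(
        bundle.covariates if q else np.empty((bundle.n_samples, 0)), columns=names
    )
    cov.insert(0, "IID", sample_ids)
    cov.to_csv(covariate_path, sep=sep, index=False)


def read_sample_table(path, sep: str = "\t", id_col: str = "IID") -> pd.DataFrame:
    """Read a phenotype or covariate table keyed by sample id."""
    df = pd.read_csv(path, sep=sep, dtype={id_col: str})
    if id_col not in df.columns:
        raise ParseError(f"{path}: missing id column {id_col!r}")
    if df[id_col].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return df.set_index(id_col)


def assemble_bundle(
    genotypes: GenotypeTable,
    phenotype: Optional[pd.DataFrame] = None,
    covariates: Optional[pd.DataFrame] = None,
    phenotype_col: str = "PHENOTYPE",
) -> DatasetBundle:
    """Join genotype, phenotype, and covariate tables on sample id.

    The genotype file's sample order is authoritative; any id absent from a
    side table (or extra in it) is a hard error.
    """
    ids = genotypes.sample_ids
    if phenotype is not None:
        _check_ids(ids, phenotype.index, "phenotype")
        y = phenotype.loc[ids, phenotype_col].to_numpy(dtype=float)
    elif genotypes.phenotype is not None:
        y = genotypes.phenotype
    else:
        raise IdMismatchError("no phenotype available")
    cov = None
    cov_names = None
    if covariates is not None:
        _check_ids(ids, covariates.index, "covariate")
        cov = covariates.loc[ids].to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    return DatasetBundle(
        features=genotypes.dosages,
        phenotype=y,
        covariates=cov,
        missing_mask=genotypes.missing_mask,
        feature_ids=genotypes.feature_ids,
        sample_ids=ids,
        metadata={} if cov_names is None else {"covariate_names": cov_names},
    )


def _check_ids(genotype_ids: Sequence[str], table_ids, what: str) -> None:
    gset, tset = set(genotype_ids), set(table_ids)
    if gset != tset:
        missing = sorted(gset - tset)[:5]
        extra = sorted(tset - gset)[:5]
        raise IdMismatchError(
            f"{what} table ids do not match genotype ids "
            f"(missing: {missing}, extra: {extra})"
        )


@dataclass
class RunConfig:
    """Configuration for a full run, loadable from JSON."""

    genotypes: Optional[str] = None
    genotype_format: str = "plink_raw"
    phenotype: Optional[str] = None
    covariates: Optional[str] = None
    synth: Optional[dict] = None
    p_raw: float = 0.05
    p_adj: Optional[float] = None
    p_prun: Optional[float] = None
    rounds: int = 1000
    follow_up_rounds: int = 0
    statistic: str = "lm_additive_t"
    alternative: str = "two-sided"
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.synth is None):
            raise ParseError(
                "exactly one of a genotype path or a synth config must be given"
            )
        for name in ("p_raw", "p_adj", "p_prun"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ParseError(f"{name} must be in (0, 1), got {v}")
        if self.rounds < 1:
            raise ParseError("rounds must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        extras = {k: v for k, v in payload.items() if k not in known}
        return cls(**kwargs, extras=extras)


def provenance_header(config: dict, seed) -> str:
    """Commented header lines recording version, config hash, and seed."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return (
        f"# enpp_version={__version__}\n"
        f"# config_sha256={digest}\n"
        f"# seed={seed}\n"
    )
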