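"""Readers and writers for genotype/phenotype tables and run configs.

Canonical genotype format: plain CSV with ``line_id`` as the first column
and one column per marker (allele dosage 0/1/2, fractional allowed).  The
PLINK ``.raw`` export (FID IID PAT MAT SEX PHENOTYPE + one column per
marker, whitespace separated) is accepted as a convenience dialect.
Phenotype tables are CSV with mandatory ``line_id``, ``family``, ``env``
columns and one numeric column per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .solver import GenotypeMatrix

logger = logging.getLogger(__name__)

PLINK_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
MANDATORY_PHENO_COLS = ["line_id", "family", "env"]


@dataclass
class PhenotypeTable:
    """Per-record family label, environment label and trait values.

    One row per line-by-environment record (a line evaluated in several
    environments contributes several rows).  ``truth`` optionally carries
    simulation ground truth (QTL indices/effects and genetic values).
    """

    df: pd.DataFrame
    truth: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_PHENO_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks mandatory columns: "
                             f"{missing}")
        for t in self.trait_names:
            if self.df[t].isna().all():
                raise ValueError(f"trait column '{t}' is empty")

    @property
    def trait_names(self) -> list:
        return [c for c in self.df.columns
                if c not in MANDATORY_PHENO_COLS
                and np.issubdtype(self.df[c].dtype, np.number)]

    @property
    def families(self) -> np.ndarray:
        return self.df["family"].to_numpy()

    @property
    def envs(self) -> np.ndarray:
        return self.df["env"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


def read_genotypes(path, fmt: str = "csv") -> GenotypeMatrix:
    """Load a dosage matrix; missing cells are mean-imputed per marker."""
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        id_col = df.columns[0]
        line_ids = df[id_col].astype(str).to_numpy()
        mat = df.drop(columns=[id_col])
    elif fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        missing = [c for c in PLINK_LEADING if c not in df.columns]
        if missing:
            raise ValueError(f".raw file lacks leading columns: {missing}")
        line_ids = df["IID"].astype(str).to_numpy()
        mat = df.drop(columns=PLINK_LEADING)
    else:
        raise ValueError("fmt must be 'csv' or 'plink_raw'")
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("duplicate line IDs in genotype file")
    try:
        values = mat.apply(pd.to_numeric).to_numpy(dtype=np.float64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric genotype cells in {path}: {exc}") from exc
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        col_means = np.nanmean(values, axis=0)
        if np.isnan(col_means).any():
            raise ValueError("marker with all dosages missing; cannot impute")
        idx = np.where(np.isnan(values))
        values[idx] = col_means[idx[1]]
        logger.info("imputed %d missing dosages to marker means", n_missing)
    return GenotypeMatrix(values=values, line_ids=line_ids,
                          marker_ids=mat.columns.to_numpy(dtype=object))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.values, columns=geno.marker_ids)
    df.insert(0, "line_id", geno.line_ids)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round-trip


def read_phenotypes(path, traits=None) -> PhenotypeTable:
    """Load a phenotype table; ``traits`` restricts/validates trait columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_PHENO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks mandatory columns: {missing}")
    df["line_id"] = df["line_id"].astype(str)
    trait_cols = (list(traits) if traits is not None else
                  [c for c in df.columns if c not in MANDATORY_PHENO_COLS])
    for t in trait_cols:
        if t not in df.columns:
            raise ValueError(f"trait column '{t}' not in {path}")
        df[t] = pd.to_numeric(df[t], errors="raise")
        if df[t].isna().all():
            raise ValueError(f"trait column '{t}' is empty")
    keep = MANDATORY_PHENO_COLS + trait_cols
    return PhenotypeTable(df=df[keep].copy())


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False, float_format="%.17g")


def align_phenotypes(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Match phenotype records to genotype rows by line ID.

    Returns ``(df, geno_rows)`` where ``geno_rows[i]`` is the genotype row of
    phenotype record ``i``; records without a genotype are dropped with a
    logged warning.
    """
    pos = {lid: i for i, lid in enumerate(geno.line_ids)}
    df = pheno.df
    hit = df["line_id"].map(pos)
    n_drop = int(hit.isna().sum())
    if n_drop:
        logger.warning("dropping %d phenotype records lacking a genotype",
                       n_drop)
        df = df[hit.notna()].reset_index(drop=True)
        hit = hit.dropna()
    return df.reset_index(drop=True), hit.to_numpy(dtype=int)


def load_run_config(path) -> RunConfig:
    """RunConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config YAML must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
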