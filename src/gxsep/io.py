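"""Readers, writers and analysis configuration.

Phenotypes come in as CSV (one row per participant), genotypes as a dosage
TSV (rows = samples, columns = rsIDs, values in [0, 2]) or as VCF — the VCF
path uses cyvcf2 when available and extracts the imputed dosage (``DS``
FORMAT field) or, failing that, the hard-called ALT allele count from
``GT``. Column orientation metadata (counted allele = ALT, other = REF) is
returned alongside so risk-allele orientation is never guessed.

The analysis population is the intersection of genotyped and phenotyped
samples; exclusions are logged, never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gxsep")

__all__ = [
    "AnalysisConfig",
    "read_phenotypes",
    "read_genotypes",
    "intersect_samples",
    "REQUIRED_PHENOTYPE_COLUMNS",
]

#: canonical phenotype fields the pipeline understands
REQUIRED_PHENOTYPE_COLUMNS = ("mgus", "age", "male")
OPTIONAL_PHENOTYPE_COLUMNS = (
    "education_years",
    "household_income",
    "household_weight",
    "smoking_ever",
    "bmi",
    "glucose",
    "fasting",
    "diabetes_history",
    "glucose_drugs",
    "ffq_fish",
    "ffq_boiled_veg",
    "ffq_raw_veg",
    "ffq_fruit",
)
_CATEGORICAL_FIELDS = {"ffq_fish", "ffq_boiled_veg", "ffq_raw_veg", "ffq_fruit"}


@dataclass
class AnalysisConfig:
    """Everything needed to re-run one analysis end to end.

    Defaults reproduce the published specification: education dichotomised
    at 14 years, income at the sex-specific median, per-allele GRS
    increment, delta-method RERI CIs.
    """

    phenotype_path: str = "phenotypes.csv"
    genotype_path: str = "genotypes.tsv"
    genotype_format: str = "tsv"  # or "vcf"
    panel_path: str = "panel.tsv"
    column_mapping: dict[str, str] = field(default_factory=dict)
    sep_indicator: str = "education"  # or "income"
    education_high_cut: float = 14.0
    grs_increment: float = 1.0
    ci_method: str = "delta"
    bootstrap_reps: int = 500
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls(**obj)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_phenotypes(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and type the phenotype CSV.

    ``column_mapping`` maps canonical field names to the file's column
    names. Numeric fields with unparseable cells become missing, with a
    per-column count logged. The first column (or ``sample_id``) indexes
    samples.
    """
    df = pd.read_csv(path, dtype=str)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        df = df.set_index(df.columns[0])
    if column_mapping:
        rename = {v: k for k, v in column_mapping.items()}
        missing = [v for v in column_mapping.values() if v not in df.columns]
        if missing:
            raise ValueError(
                f"mapped column(s) {missing} absent from {path}; available "
                f"columns: {list(df.columns)}"
            )
        df = df.rename(columns=rename)
    for col in REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise ValueError(
                f"required column {col!r} not found in {path}; available "
                f"columns: {list(df.columns)}"
            )
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        if col in _CATEGORICAL_FIELDS:
            out[col] = df[col].where(df[col].notna() & (df[col] != ""), other=pd.NA)
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        n_bad = int((parsed.isna() & df[col].notna() & (df[col] != "")).sum())
        if n_bad:
            logger.info("column %s: %d unparseable cell(s) set to missing", col, n_bad)
        out[col] = parsed
    return out


def _read_genotypes_tsv(path: str | Path) -> tuple[pd.DataFrame, None]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    _validate_dosages(df)
    return df, None


def _read_genotypes_vcf(path: str | Path) -> tuple[pd.DataFrame, dict]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    allele_info: dict[str, tuple[str, str]] = {}
    for var in vcf:
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols[rsid] = dos
        allele_info[rsid] = (var.ALT[0] if var.ALT else ".", var.REF)
    df = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    _validate_dosages(df)
    return df, allele_info


def _validate_dosages(df: pd.DataFrame) -> None:
    arr = df.to_numpy(dtype=float)
    bad = np.nonzero((arr < -1e-9) | (arr > 2 + 1e-9))
    if len(bad[0]):
        i, j = bad[0][0], bad[1][0]
        raise ValueError(
            f"dosage {arr[i, j]} outside [0, 2] at sample {df.index[i]!r}, "
            f"locus {df.columns[j]!r}"
        )


def read_genotypes(
    path: str | Path, format: str = "tsv"
) -> tuple[pd.DataFrame, dict | None]:
    """Read a dosage matrix; returns (samples × rsIDs frame, allele_info).

    ``allele_info`` maps rsid -> (counted_allele, other_allele) for VCF
    input (counted = ALT); TSV input carries no allele metadata (``None``)
    and is assumed risk-allele-oriented.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def intersect_samples(
    phenotypes: pd.DataFrame, genotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to their common samples (the analysis population).

    Samples on one side only are excluded and logged.
    """
    common = phenotypes.index.intersection(genotypes.index)
    geno_only = genotypes.index.difference(phenotypes.index)
    pheno_only = phenotypes.index.difference(genotypes.index)
    if len(geno_only):
        logger.info("%d sample(s) genotyped but not phenotyped: excluded", len(geno_only))
    if len(pheno_only):
        logger.info("%d sample(s) phenotyped but not genotyped: excluded", len(pheno_only))
    return phenotypes.loc[common], genotypes.loc[common]
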