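"""File dialects, readers/writers and cohort assembly.

All tables are tab-separated UTF-8 with a single header row and missing token
"NA" (the norm for GWAS summary files).  Each dialect declares its required
columns, which are validated on read and on write; unknown columns are
preserved on round-trip.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class FileDialect:
    name: str
    required_columns: tuple[str, ...]


DIALECTS = {
    "cohort-tsv": FileDialect("cohort-tsv", ("iid",)),
    "geno-tsv": FileDialect("geno-tsv", ("iid",)),
    "weights-tsv": FileDialect(
        "weights-tsv", ("snp", "effect_allele", "other_allele", "weight")
    ),
    "sumstats-tsv": FileDialect(
        "sumstats-tsv",
        (
            "snp",
            "effect_allele",
            "other_allele",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
        ),
    ),
    "gwas-tsv": FileDialect(
        "gwas-tsv", ("snp", "effect_allele", "other_allele", "beta", "se")
    ),
    "scores-tsv": FileDialect("scores-tsv", ("iid",)),
    "results-tsv": FileDialect(
        "results-tsv",
        (
            "model_kind",
            "exposure",
            "outcome",
            "stratum",
            "n",
            "beta",
            "se",
            "ci_low",
            "ci_high",
            "p",
        ),
    ),
}


class TableFormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _dialect(dialect: str | FileDialect) -> FileDialect:
    if isinstance(dialect, FileDialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise TableFormatError(f"unknown dialect '{dialect}'") from None


def read_table(path, dialect: str | FileDialect) -> pd.DataFrame:
    """Read a TSV table, validating required columns and mapping "NA"/empty to missing."""
    d = _dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False)
    missing = [c for c in d.required_columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path} ({d.name}): missing required column(s) {missing}"
        )
    logger.info("read %d rows from %s (%s)", len(df), path, d.name)
    return df


def write_table(df: pd.DataFrame, path, dialect: str | FileDialect) -> None:
    """Write a TSV table after a schema check against the dialect."""
    d = _dialect(dialect)
    missing = [c for c in d.required_columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"refusing to write {d.name} without column(s) {missing}"
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_genotypes(path) -> "GenotypeMatrix":
    """Read a genotype dosage TSV (first column iid, one column per SNP)."""
    from .genetics import GenotypeMatrix

    df = read_table(path, "geno-tsv").set_index("iid")
    return GenotypeMatrix(
        individual_ids=list(df.index.astype(str)),
        snp_ids=list(df.columns.astype(str)),
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf_dosages(path) -> "GenotypeMatrix":
    """Read effect-allele dosages from a VCF.

    Uses the DS FORMAT field when present; otherwise computes the dosage as
    the ALT allele count from GT, with half-calls and missing genotypes
    mapped to missing.  Dosages are reported on the ALT allele.
    """
    from cyvcf2 import VCF

    from .genetics import GenotypeMatrix

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            dose = np.full(len(samples), np.nan)
            for i, gt in enumerate(var.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles) or len(alleles) != 2:
                    continue  # missing or half-call
                dose[i] = sum(1 for a in alleles if a > 0)
            rows.append(dose)
    if not snp_ids:
        raise TableFormatError(f"no variants found in {path}")
    return GenotypeMatrix(
        individual_ids=samples, snp_ids=snp_ids, dosages=np.array(rows).T
    )


def merge_cohort(
    phenotypes: pd.DataFrame,
    scores: Optional[pd.DataFrame] = None,
    genotypes: Optional[pd.DataFrame] = None,
    require_any_of: Optional[Sequence[str]] = None,
    id_col: str = "iid",
) -> pd.DataFrame:
    """Inner-join phenotypes, scores and (optionally) genotypes on individual ID.

    ``require_any_of`` implements the eligibility rule "has at least one of
    these columns non-missing" (e.g. at least one measured outcome); rows
    failing it are dropped with a logged count.  Duplicate IDs in any input
    are an error; join losses are logged.
    """
    frames = [("phenotypes", phenotypes)]
    if scores is not None:
        frames.append(("scores", scores))
    if genotypes is not None:
        frames.append(("genotypes", genotypes))
    for name, df in frames:
        if id_col not in df.columns:
            raise TableFormatError(f"{name} table lacks ID column '{id_col}'")
        if df[id_col].duplicated().any():
            raise TableFormatError(f"duplicate IDs in {name} table")
    merged = phenotypes
    for name, df in frames[1:]:
        before = len(merged)
        merged = merged.merge(df, on=id_col, how="inner")
        lost = before - len(merged)
        if lost:
            logger.info("merge with %s dropped %d row(s) without a match", name, lost)
    if merged.empty:
        raise TableFormatError("cohort merge produced zero rows (disjoint ID sets?)")
    if require_any_of:
        have = merged[list(require_any_of)].notna().any(axis=1)
        dropped = int((~have).sum())
        if dropped:
            logger.info(
                "eligibility filter (any of %s) dropped %d row(s)",
                list(require_any_of), dropped,
            )
        merged = merged[have]
    return merged.reset_index(drop=True)


def load_config(path) -> dict:
    """Load a declarative key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TableFormatError(f"config {path} must be a mapping at top level")
    return cfg


def file_checksum(path) -> str:
    """SHA256 of a file, for run-log provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
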