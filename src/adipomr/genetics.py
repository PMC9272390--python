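"""Genetic risk score construction and standardisation.

The scoring rule is the standard one for polygenic instruments: multiply the
effect-allele dosage at each SNP by its GWAS weight, sum over SNPs, and divide
by the number of SNPs used, so the score reflects the average per-SNP effect
on the exposure.  Scores are z-standardised before use as instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VALID_BASES = set("ACGT")


class InputError(ValueError):
    """Raised for malformed or incompatible genetic inputs."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages, values in [0, 2].

    Dosages are stored as a dense array (int8 for hard calls, float for
    imputed values, NaN for missing).  IDs must be unique on both axes.
    """

    individual_ids: Sequence[str]
    snp_ids: Sequence[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise InputError("dosage matrix shape does not match ID lists")
        if len(set(self.individual_ids)) != n:
            raise InputError("duplicate individual IDs")
        if len(set(self.snp_ids)) != m:
            raise InputError("duplicate SNP IDs")
        vals = self.dosages[~np.isnan(self.dosages.astype(float))]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise InputError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=list(self.individual_ids), columns=list(self.snp_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            individual_ids=list(df.index.astype(str)),
            snp_ids=list(df.columns.astype(str)),
            dosages=df.to_numpy(),
        )


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a SNP-weights table (columns: snp, effect_allele, other_allele, weight)."""
    required = {"snp", "effect_allele", "other_allele", "weight"}
    missing = required - set(weights.columns)
    if missing:
        raise InputError(f"weights table missing columns: {sorted(missing)}")
    if weights["snp"].duplicated().any():
        dups = weights.loc[weights["snp"].duplicated(), "snp"].tolist()
        raise InputError(f"duplicate SNP(s) in weights: {dups[:5]}")
    for col in ("effect_allele", "other_allele"):
        alleles = weights[col].astype(str)
        bad = ~alleles.str.fullmatch(r"[ACGT]+")
        if bad.any():
            raise InputError(
                f"invalid allele(s) in column '{col}': "
                f"{alleles[bad].unique()[:5].tolist()}"
            )
    return weights


@dataclass
class RiskScore:
    """Per-individual genetic risk score (average per-SNP weighted dosage)."""

    individual_ids: Sequence[str]
    score: np.ndarray
    n_snps_used: int
    snps_missing: list[str] = field(default_factory=list)

    def to_series(self, name: str = "grs") -> pd.Series:
        return pd.Series(self.score, index=list(self.individual_ids), name=name)


def build_grs(
    geno: GenotypeMatrix,
    weights: pd.DataFrame,
    allow_missing: float = 0.0,
    strict: bool = False,
) -> RiskScore:
    """Construct a genetic risk score from dosages and SNP weights.

    score_i = sum_j w_j * d_ij / m, where m is the number of SNPs used.
    Weight SNPs absent from the genotype matrix are excluded; if their
    fraction exceeds ``allow_missing`` an :class:`InputError` is raised.

    Missing dosages (NaN): by default an individual's score is averaged over
    their observed SNPs (per-individual denominator), matching the
    average-per-SNP-effect semantics; with ``strict=True`` any missing dosage
    raises instead.
    """
    weights = validate_weights(weights)
    pos = {s: i for i, s in enumerate(geno.snp_ids)}
    present_mask = weights["snp"].map(pos.__contains__)
    absent = weights.loc[~present_mask, "snp"].tolist()
    used = weights[present_mask]
    if used.empty:
        raise InputError("no weight SNPs overlap the genotype matrix")
    frac_missing = len(absent) / len(weights)
    if frac_missing > allow_missing:
        raise InputError(
            f"{len(absent)}/{len(weights)} weight SNPs absent from genotypes "
            f"({frac_missing:.1%} > allow_missing={allow_missing:.1%})"
        )

    cols = [pos[s] for s in used["snp"]]
    d = geno.dosages[:, cols].astype(float)
    w = used["weight"].to_numpy(dtype=float)
    observed = ~np.isnan(d)
    if strict and not observed.all():
        raise InputError("missing dosages present and strict=True")
    weighted = np.where(observed, d, 0.0) @ w.reshape(-1, 1)
    m_i = observed.sum(axis=1)
    if (m_i == 0).any():
        raise InputError("some individuals have no observed dosage at any weight SNP")
    score = weighted.ravel() / m_i
    return RiskScore(
        individual_ids=list(geno.individual_ids),
        score=score,
        n_snps_used=len(used),
        snps_missing=absent,
    )


def standardise(values: pd.Series | np.ndarray, name: Optional[str] = None) -> pd.Series:
    """z-standardise a column: subtract the mean, divide by the sample SD (n-1).

    Missing entries are ignored in the moments and stay missing in the output.
    Raises :class:`InputError` for a (near-)constant column, naming it.
    """
    s = pd.Series(values) if not isinstance(values, pd.Series) else values
    label = name or s.name or "<unnamed>"
    obs = s.dropna()
    if obs.nunique() < 2:
        raise InputError(f"cannot standardise constant column '{label}'")
    sd = obs.std(ddof=1)
    return (s - obs.mean()) / sd


def grs_correlation(score_a: RiskScore, score_b: RiskScore) -> float:
    """Pearson correlation of two risk scores on the intersection of individuals."""
    a = score_a.to_series("a")
    b = score_b.to_series("b")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InputError(
            f"need >= 3 shared individuals to correlate scores, got {len(shared)}"
        )
    return float(np.corrcoef(a.loc[shared], b.loc[shared])[0, 1])
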