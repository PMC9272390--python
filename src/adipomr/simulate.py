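"""Seeded synthetic cohorts with the causal structure assumed by the adiposity MR design.

The generator produces individual-level data emulating a large biobank-style
cohort: polygenic biallelic instruments, two correlated adiposity exposures
(BMI, general adiposity; WHR, central adiposity) with a causal BMI->WHR path,
metabolite outcomes driven by one or both exposures plus a shared confounder,
and statin use generated from the exposures and latent LDL cholesterol with a
treatment effect that lowers *measured* LDL-C.  Statin prevalence rises with
age, so age stratification proxies medication exposure.

Every generative coefficient is recorded in a truth object so downstream
estimators can be scored for parameter recovery, and the population moments
implied by the configuration (exposure covariance, total effects, expected
genetic-score correlation) are available in closed form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))

#: default direct effects (per SD of exposure, SD units of outcome) of BMI and
#: WHR on each simulated metabolite.  Triglycerides are driven by central
#: adiposity only; latent LDL-C modestly by WHR; the inflammatory marker GlycA
#: by both.
DEFAULT_THETA_BMI = {"trig": 0.0, "ldl": 0.0, "glyca": 0.15}
DEFAULT_THETA_WHR = {"trig": 0.6, "ldl": 0.15, "glyca": 0.25}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Exposures and latent outcomes are generated with unit variance in
    expectation, so all path coefficients are on the standardised (SD) scale.

    Attributes
    ----------
    n_individuals : int
        Cohort size.
    n_snps_bmi, n_snps_whr : int
        Number of SNPs affecting only BMI / only WHR.
    n_snps_shared : int
        SNPs with direct effects on both exposures.  Shared SNPs induce a
        genetic correlation between the two risk scores; the default preset
        keeps the instrument sets disjoint so that the univariable BMI
        estimand is exactly ``theta_bmi + delta_bmi_to_whr * theta_whr``.
    maf_range : (float, float)
        Minor-allele-frequency window, each bound in (0, 0.5].
    h2_bmi, h2_whr : float
        Variance fraction of each exposure explained by its own SNP set
        (plus shared SNPs), in [0, 1).
    delta_bmi_to_whr : float
        Causal path BMI -> WHR (SD per SD).
    theta_bmi, theta_whr : mapping outcome name -> float
        Direct effects of each exposure on each latent outcome.
    kappa_confounder : float
        Loading of the standard-normal confounder U on every outcome.
    kappa_bmi, kappa_whr : float
        Loadings of U on the exposures (this is what makes conventional
        regression estimates confounded while MR stays consistent).
    statin_intercept : float
        Logit-scale intercept of statin use at the cohort mean age.
    statin_slope_bmi, statin_slope_whr, statin_slope_ldl : float
        Logit-scale effects of BMI, WHR and latent LDL-C on statin use.
    tau_statin : float
        Constant LDL-lowering treatment effect of statin use, in SD units of
        LDL-C; measured LDL-C = latent LDL-C - tau_statin * statin.
    age_range : (float, float)
        Uniform age window in years (age is independent of genotype and
        adiposity by construction).
    age_statin_gradient : float
        Logit-scale per-year age effect on statin use.
    sex_effect_overrides : optional mapping
        ``{"male": {"theta_bmi": {...}, "theta_whr": {...}}, "female": ...}``
        replacing exposure->outcome effects per sex; sex is Bernoulli(0.5)
        coded 0=male, 1=female.  Allele effects are never sex-specific.
    ldl_outcome : str
        Name of the outcome treated as LDL-C (receives the statin machinery).
    seed : int
        Seed for all randomness; a fixed config is byte-reproducible.
    """

    n_individuals: int = 20_000
    n_snps_bmi: int = 60
    n_snps_whr: int = 60
    n_snps_shared: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_bmi: float = 0.10
    h2_whr: float = 0.10
    delta_bmi_to_whr: float = 0.4
    theta_bmi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA_BMI))
    theta_whr: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA_WHR))
    kappa_confounder: float = 0.3
    kappa_bmi: float = 0.3
    kappa_whr: float = 0.3
    statin_intercept: float = -2.3
    statin_slope_bmi: float = 0.3
    statin_slope_whr: float = 0.5
    statin_slope_ldl: float = 1.2
    tau_statin: float = 1.5
    age_range: tuple[float, float] = (38.0, 73.0)
    age_statin_gradient: float = 0.10
    sex_effect_overrides: Optional[Mapping[str, Mapping[str, Mapping[str, float]]]] = None
    ldl_outcome: str = "ldl"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        for name in ("h2_bmi", "h2_whr"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for name in ("n_snps_bmi", "n_snps_whr"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_snps_shared < 0:
            raise ConfigurationError("n_snps_shared must be >= 0")
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if set(self.theta_bmi) != set(self.theta_whr):
            raise ConfigurationError(
                "theta_bmi and theta_whr must name the same outcomes"
            )

    @property
    def outcomes(self) -> list[str]:
        return list(self.theta_bmi)

    # ---- closed-form population moments implied by the configuration ----

    @property
    def n_snps_bmi_total(self) -> int:
        return self.n_snps_bmi + self.n_snps_shared

    @property
    def n_snps_whr_total(self) -> int:
        return self.n_snps_whr + self.n_snps_shared

    @property
    def genetic_covariance(self) -> float:
        """Cov(G_bmi, G_whr) from shared SNPs, with equal per-SNP variance shares."""
        if self.n_snps_shared == 0:
            return 0.0
        return self.n_snps_shared * np.sqrt(
            self.h2_bmi * self.h2_whr / (self.n_snps_bmi_total * self.n_snps_whr_total)
        )

    @property
    def expected_grs_correlation(self) -> float:
        if self.h2_bmi == 0 or self.h2_whr == 0:
            return 0.0
        return self.genetic_covariance / np.sqrt(self.h2_bmi * self.h2_whr)

    @property
    def cov_bmi_whr(self) -> float:
        """Population Cov(BMI, WHR) = delta + shared genetics + shared confounding."""
        return self.delta_bmi_to_whr + self.genetic_covariance + self.kappa_bmi * self.kappa_whr

    def total_effect_bmi(self, outcome: str) -> float:
        """Univariable (total) BMI estimand when the score sets are disjoint."""
        return self.theta_bmi[outcome] + self.delta_bmi_to_whr * self.theta_whr[outcome]

    def total_effect_whr(self, outcome: str) -> float:
        """WHR has no back-path onto BMI, so its total effect equals its direct one."""
        return self.theta_whr[outcome]


@dataclass
class Truth:
    """Record of all generative coefficients — the estimands for scoring recovery."""

    config: SimConfig
    snp_ids: list[str]
    allele_freqs: np.ndarray
    beta_bmi: np.ndarray  # per-allele effect of each SNP on BMI (0 where none)
    beta_whr: np.ndarray
    residual_sd_bmi: float
    residual_sd_whr: float
    residual_sd_outcomes: dict[str, float]

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["theta_bmi"] = dict(self.config.theta_bmi)
        cfg["theta_whr"] = dict(self.config.theta_whr)
        return {
            "config": cfg,
            "snp_ids": list(self.snp_ids),
            "allele_freqs": self.allele_freqs.tolist(),
            "beta_bmi": self.beta_bmi.tolist(),
            "beta_whr": self.beta_whr.tolist(),
            "residual_sd_bmi": self.residual_sd_bmi,
            "residual_sd_whr": self.residual_sd_whr,
            "residual_sd_outcomes": dict(self.residual_sd_outcomes),
            "derived": {
                "genetic_covariance": self.config.genetic_covariance,
                "expected_grs_correlation": self.config.expected_grs_correlation,
                "cov_bmi_whr": self.config.cov_bmi_whr,
                "total_effect_bmi": {
                    k: self.config.total_effect_bmi(k) for k in self.config.outcomes
                },
                "total_effect_whr": {
                    k: self.config.total_effect_whr(k) for k in self.config.outcomes
                },
            },
        }


@dataclass
class SyntheticCohort:
    """A simulated cohort: genotypes, joined phenotype table, per-exposure SNP weights and the generative truth."""

    genotypes: "GenotypeMatrix"
    phenotypes: pd.DataFrame
    weights: dict[str, pd.DataFrame]  # exposure -> SNP-weights table
    truth: Truth


# GenotypeMatrix lives in genetics (it is the scoring-side container); import
# deferred to avoid a cycle at module import time.
from .genetics import GenotypeMatrix  # noqa: E402


def simulate_genotypes(
    n: int,
    n_snps: int,
    maf_range: tuple[float, float],
    seed: int,
    snp_prefix: str = "rs",
) -> GenotypeMatrix:
    """Draw unlinked biallelic genotypes in Hardy-Weinberg proportions.

    Each SNP j has allele frequency ``f_j ~ Uniform(maf_range)`` and dosages
    drawn i.i.d. Binomial(2, f_j), i.e. hard calls in {0, 1, 2} with no LD
    (instrument SNPs in this design are clumped to near-independence).
    """
    if n < 1 or n_snps < 1:
        raise ConfigurationError("n and n_snps must both be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(
            f"maf_range must satisfy 0 < low <= high <= 0.5, got {maf_range}"
        )
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n, n_snps)).astype(np.int8)
    snp_ids = [f"{snp_prefix}{j + 1}" for j in range(n_snps)]
    individual_ids = [f"id{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        individual_ids=individual_ids, snp_ids=snp_ids, dosages=dosages
    )


def _per_snp_effects(h2: float, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-allele effects giving each SNP an equal share h2/m of exposure variance.

    beta_j = s_j * sqrt(h2 / (m * 2 f_j (1 - f_j))) with random sign s_j, so the
    genetic score G = sum_j beta_j d_j has variance h2 exactly in the population.
    """
    m = len(freqs)
    mags = np.sqrt(h2 / (m * 2.0 * freqs * (1.0 - freqs)))
    signs = rng.choice([-1.0, 1.0], size=m)
    return mags * signs


def _resolve_thetas(cfg: SimConfig, sex: np.ndarray, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual (theta_bmi, theta_whr) for one outcome, honouring sex overrides."""
    tb = np.full(sex.shape, cfg.theta_bmi[outcome], dtype=float)
    tw = np.full(sex.shape, cfg.theta_whr[outcome], dtype=float)
    if cfg.sex_effect_overrides:
        for label, mask in (("male", sex == 0), ("female", sex == 1)):
            ov = cfg.sex_effect_overrides.get(label)
            if not ov:
                continue
            if outcome in ov.get("theta_bmi", {}):
                tb[mask] = ov["theta_bmi"][outcome]
            if outcome in ov.get("theta_whr", {}):
                tw[mask] = ov["theta_whr"][outcome]
    return tb, tw


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured causal model.

    The structural equations (all variables except age/sex/dosages are
    standardised in expectation) are::

        BMI  = G_bmi + kappa_bmi * U + e_bmi
        WHR  = G_whr + delta * BMI + kappa_whr * U + e_whr
        Y*_k = theta_bmi_k * BMI + theta_whr_k * WHR + kappa * U + e_k
        S    ~ Bernoulli(expit(a + b_bmi*BMI + b_whr*WHR + b_ldl*Y*_LDL
                               + g_age*(age - mean age)))
        LDL  = Y*_LDL - tau_statin * S          (measured LDL-C)

    with U ~ N(0,1) shared across all equations, and residual variances chosen
    so each exposure/latent outcome has unit population variance.  Raises
    :class:`ConfigurationError` naming the offending parameter whenever an
    implied residual variance is non-positive.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals

    # genotypes: BMI-only SNPs, WHR-only SNPs, then shared SNPs (drawn inline so
    # the generative allele frequencies are available exactly for the truth record)
    m_total = cfg.n_snps_bmi + cfg.n_snps_whr + cfg.n_snps_shared
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=m_total)
    dosages = rng.binomial(2, freqs, size=(n, m_total)).astype(np.int8)
    snp_ids = [f"rs{j + 1}" for j in range(m_total)]
    individual_ids = [f"id{i + 1}" for i in range(n)]
    geno = GenotypeMatrix(individual_ids=individual_ids, snp_ids=snp_ids, dosages=dosages)

    idx_b = np.arange(0, cfg.n_snps_bmi)
    idx_w = np.arange(cfg.n_snps_bmi, cfg.n_snps_bmi + cfg.n_snps_whr)
    idx_s = np.arange(cfg.n_snps_bmi + cfg.n_snps_whr, m_total)

    beta_bmi = np.zeros(m_total)
    beta_whr = np.zeros(m_total)
    bmi_set = np.concatenate([idx_b, idx_s])
    whr_set = np.concatenate([idx_w, idx_s])
    beta_bmi[bmi_set] = _per_snp_effects(cfg.h2_bmi, freqs[bmi_set], rng)
    beta_whr[whr_set] = _per_snp_effects(cfg.h2_whr, freqs[whr_set], rng)
    # shared SNPs get aligned signs so shared variance yields a positive
    # score correlation (as observed between real BMI and WHR scores)
    if len(idx_s):
        beta_whr[idx_s] = np.sign(beta_bmi[idx_s]) * np.abs(beta_whr[idx_s])

    centred = dosages.astype(float) - 2.0 * freqs
    g_bmi = centred @ beta_bmi
    g_whr = centred @ beta_whr

    u = rng.standard_normal(n)

    var_e_bmi = 1.0 - cfg.h2_bmi - cfg.kappa_bmi**2
    if var_e_bmi <= 0:
        raise ConfigurationError(
            "implied BMI residual variance <= 0 (check h2_bmi and kappa_bmi)"
        )
    bmi = g_bmi + cfg.kappa_bmi * u + rng.standard_normal(n) * np.sqrt(var_e_bmi)

    c_g = cfg.genetic_covariance
    delta = cfg.delta_bmi_to_whr
    var_e_whr = (
        1.0
        - cfg.h2_whr
        - delta**2
        - cfg.kappa_whr**2
        - 2.0 * delta * (c_g + cfg.kappa_bmi * cfg.kappa_whr)
    )
    if var_e_whr <= 0:
        raise ConfigurationError(
            "implied WHR residual variance <= 0 "
            "(check h2_whr, delta_bmi_to_whr and kappa_whr)"
        )
    whr = (
        g_whr
        + delta * bmi
        + cfg.kappa_whr * u
        + rng.standard_normal(n) * np.sqrt(var_e_whr)
    )

    sex = rng.integers(0, 2, size=n)  # 0=male, 1=female
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    rho_bw = cfg.cov_bmi_whr
    cov_bmi_u = cfg.kappa_bmi
    cov_whr_u = cfg.kappa_whr + delta * cfg.kappa_bmi

    outcomes: dict[str, np.ndarray] = {}
    residual_sd_outcomes: dict[str, float] = {}
    kap = cfg.kappa_confounder
    for name in cfg.outcomes:
        tb_pop = cfg.theta_bmi[name]
        tw_pop = cfg.theta_whr[name]
        explained = (
            tb_pop**2
            + tw_pop**2
            + 2.0 * tb_pop * tw_pop * rho_bw
            + kap**2
            + 2.0 * kap * (tb_pop * cov_bmi_u + tw_pop * cov_whr_u)
        )
        var_e = 1.0 - explained
        if var_e <= 0:
            raise ConfigurationError(
                f"implied residual variance <= 0 for outcome '{name}' "
                f"(theta_bmi={tb_pop}, theta_whr={tw_pop}, kappa={kap})"
            )
        tb, tw = _resolve_thetas(cfg, sex, name)
        outcomes[name] = (
            tb * bmi + tw * whr + kap * u + rng.standard_normal(n) * np.sqrt(var_e)
        )
        residual_sd_outcomes[name] = float(np.sqrt(var_e))

    # statin use: logistic in BMI, WHR, latent LDL-C and (centred) age
    ldl_latent = outcomes.get(cfg.ldl_outcome)
    mean_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    eta = (
        cfg.statin_intercept
        + cfg.statin_slope_bmi * bmi
        + cfg.statin_slope_whr * whr
        + cfg.age_statin_gradient * (age - mean_age)
    )
    if ldl_latent is not None:
        eta = eta + cfg.statin_slope_ldl * ldl_latent
    statin = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)

    pheno = pd.DataFrame({"iid": individual_ids})
    pheno["sex"] = sex.astype(np.int8)
    pheno["age"] = age
    pcs = rng.standard_normal((n, 10))
    for k, col in enumerate(PC_COLUMNS):
        pheno[col] = pcs[:, k]
    # crude socio-behavioural stand-ins correlated with the confounder; used
    # only by the conventional (non-instrumented) comparison models
    pheno["education"] = np.clip(
        np.digitize(0.5 * u + rng.standard_normal(n), [-1.5, -0.5, 0.5, 1.5]), 0, 4
    ).astype(np.int8)
    pheno["smoking"] = np.clip(
        np.digitize(-0.4 * u + rng.standard_normal(n), [0.5, 1.5]), 0, 2
    ).astype(np.int8)
    pheno["alcohol"] = np.clip(
        np.digitize(0.3 * u + rng.standard_normal(n), [-1.5, -0.5, 0.5, 1.5]), 0, 4
    ).astype(np.int8)
    pheno["bmi"] = bmi
    pheno["whr"] = whr
    pheno["statin"] = statin
    for name, vals in outcomes.items():
        if name == cfg.ldl_outcome:
            pheno[f"{name}_latent"] = vals
            pheno[name] = vals - cfg.tau_statin * statin
        else:
            pheno[name] = vals

    weights = {
        "bmi": _weights_frame(snp_ids, beta_bmi, bmi_set),
        "whr": _weights_frame(snp_ids, beta_whr, whr_set),
    }

    truth = Truth(
        config=cfg,
        snp_ids=snp_ids,
        allele_freqs=freqs,
        beta_bmi=beta_bmi,
        beta_whr=beta_whr,
        residual_sd_bmi=float(np.sqrt(var_e_bmi)),
        residual_sd_whr=float(np.sqrt(var_e_whr)),
        residual_sd_outcomes=residual_sd_outcomes,
    )
    return SyntheticCohort(genotypes=geno, phenotypes=pheno, weights=weights, truth=truth)


def _weights_frame(snp_ids: Sequence[str], betas: np.ndarray, idx: np.ndarray) -> pd.DataFrame:
    """SNP-weights table (effect allele arbitrarily 'A', other 'G')."""
    return pd.DataFrame(
        {
            "snp": [snp_ids[j] for j in idx],
            "effect_allele": "A",
            "other_allele": "G",
            "weight": betas[idx],
        }
    )


def make_summary_stats(
    cohort: SyntheticCohort,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = (),
    snps: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-SNP association summaries of an exposure and an outcome.

    For every SNP, the exposure and the outcome are each regressed on the
    effect-allele dosage plus the named covariates (with intercept), and the
    dosage coefficient and its classical OLS standard error are reported —
    the layout of a pair of GWAS summary files already merged on SNP.

    Computation uses the Frisch-Waugh-Lovell reduction (residualise once on
    the shared covariates, then one slope per SNP) which is algebraically
    identical to per-SNP full regressions, including the degrees of freedom.

    Constant dosage columns are dropped with a logged warning.
    """
    pheno = cohort.phenotypes
    for col in (exposure, outcome, *covariates):
        if col not in pheno.columns:
            raise KeyError(f"column '{col}' not present in cohort phenotypes")
    geno = cohort.genotypes
    if snps is None:
        snps = list(geno.snp_ids)
    pos = {s: i for i, s in enumerate(geno.snp_ids)}
    missing = [s for s in snps if s not in pos]
    if missing:
        raise KeyError(f"SNPs not in genotype matrix: {missing[:5]}")

    d = geno.dosages[:, [pos[s] for s in snps]].astype(float)
    x = pheno[exposure].to_numpy(dtype=float)
    y = pheno[outcome].to_numpy(dtype=float)
    n = len(x)
    c = np.column_stack(
        [np.ones(n)] + [pheno[cv].to_numpy(dtype=float) for cv in covariates]
    )
    k_cov = c.shape[1]
    # residualise everything on covariates (FWL)
    q, _ = np.linalg.qr(c)
    proj = lambda v: v - q @ (q.T @ v)  # noqa: E731
    xr = proj(x)
    yr = proj(y)
    dr = d - q @ (q.T @ d)

    ss_d = (dr**2).sum(axis=0)
    keep = ss_d > 1e-12
    if not keep.all():
        dropped = [s for s, k in zip(snps, keep) if not k]
        logger.warning("dropping %d constant dosage column(s): %s", len(dropped), dropped[:5])
    snps = [s for s, k in zip(snps, keep) if k]
    dr = dr[:, keep]
    ss_d = ss_d[keep]

    dof = n - k_cov - 1
    rows = []
    bx = dr.T @ xr / ss_d
    by = dr.T @ yr / ss_d
    # residual variance of the *full* per-SNP model, computed via FWL residuals
    rss_x = (xr**2).sum() - bx**2 * ss_d
    rss_y = (yr**2).sum() - by**2 * ss_d
    se_x = np.sqrt(rss_x / dof / ss_d)
    se_y = np.sqrt(rss_y / dof / ss_d)
    eaf = d[:, keep].mean(axis=0) / 2.0
    for j, s in enumerate(snps):
        rows.append(
            {
                "snp": s,
                "effect_allele": "A",
                "other_allele": "G",
                "beta_exposure": bx[j],
                "se_exposure": se_x[j],
                "beta_outcome": by[j],
                "se_outcome": se_y[j],
                "eaf": eaf[j],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets and file output


def ukb_like_config(seed: int = 0, n_individuals: int = 20_000, **overrides) -> SimConfig:
    """The default biobank-like preset used throughout the tests and examples.

    Encodes the qualitative regime the analysis is designed to detect:
    triglycerides raised by central adiposity only (direct WHR effect 0.6 SD,
    direct BMI effect 0), a BMI->WHR path of 0.4, a modest direct WHR effect
    on LDL-C, statin uptake increasing with BMI, WHR, LDL-C and age, and a
    1.5 SD LDL-lowering treatment effect.
    """
    return SimConfig(seed=seed, n_individuals=n_individuals, **overrides)


def sex_specific_overrides() -> dict:
    """Effect overrides emulating sex-divergent triglyceride regimes:
    BMI-driven among men, WHR-driven among women."""
    return {
        "male": {"theta_bmi": {"trig": 0.3}, "theta_whr": {"trig": 0.0}},
        "female": {"theta_bmi": {"trig": 0.0}, "theta_whr": {"trig": 0.6}},
    }


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write genotype/phenotype/weights/truth files in the package's TSV dialects."""
    from pathlib import Path

    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    geno_df = cohort.genotypes.to_frame().reset_index().rename(columns={"index": "iid"})
    paths["genotypes"] = str(out / "genotypes.tsv")
    io_mod.write_table(geno_df, paths["genotypes"], dialect="geno-tsv")

    paths["phenotypes"] = str(out / "phenotypes.tsv")
    io_mod.write_table(cohort.phenotypes, paths["phenotypes"], dialect="cohort-tsv")

    for exposure, wdf in cohort.weights.items():
        key = f"weights_{exposure}"
        paths[key] = str(out / f"weights_{exposure}.tsv")
        io_mod.write_table(wdf, paths[key], dialect="weights-tsv")

    paths["truth"] = str(out / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=2)
    return paths
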