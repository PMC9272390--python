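"""Two-sample summary-statistics Mendelian randomization.

Four estimators with different pleiotropy assumptions, operating on per-SNP
(beta_exposure, beta_outcome) pairs with standard errors:

* IVW — inverse-variance-weighted mean of per-SNP Wald ratios; assumes all
  SNPs are valid instruments.  Equivalent to a zero-intercept weighted
  regression of outcome betas on exposure betas.
* MR-Egger — the same regression with a free intercept estimating average
  directional pleiotropy; all SNPs may be pleiotropic (InSIDE assumption).
* Weighted median — consistent when >= 50% of the weight comes from valid
  instruments; robust to outliers.
* Weighted mode — consistent when the largest weighted cluster of ratio
  estimates is valid ("plurality valid"); robust to outliers.

IVW uses multiplicative random-effects scaling with a fixed-effect floor
(the SE is inflated by sqrt(Q/(J-1)) when the heterogeneity statistic
exceeds its degrees of freedom, never deflated); MR-Egger uses the
unfloored weighted-least-squares dispersion with a t(J-2) reference so its
pleiotropy (intercept) test stays exactly calibrated.  Median and mode use
parametric-bootstrap SEs.

An allele harmoniser aligns outcome summaries to the exposure's effect
alleles, flipping signs where the allele pair is swapped and dropping
strand-ambiguous palindromic SNPs unless allele frequencies resolve the
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = (
    "snp",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class TwoSampleResult:
    """Result of one summary-MR estimator."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    egger_intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    bandwidth: Optional[float] = None
    n_boot: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "n_snps": self.n_snps,
            "egger_intercept": self.egger_intercept,
            "intercept_p": self.intercept_p,
        }


def _validate(stats_df: pd.DataFrame, min_snps: int, method: str) -> pd.DataFrame:
    missing = set(("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")) - set(
        stats_df.columns
    )
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    if (stats_df["se_exposure"] <= 0).any() or (stats_df["se_outcome"] <= 0).any():
        raise ValueError("standard errors must be strictly positive")
    df = stats_df.copy()
    zero = df["beta_exposure"] == 0
    if zero.any():
        logger.warning(
            "%s: excluding %d SNP(s) with beta_exposure == 0", method, int(zero.sum())
        )
        df = df[~zero]
    if len(df) < min_snps:
        raise ValueError(f"{method} needs >= {min_snps} SNPs, got {len(df)}")
    return df


# ---------------------------------------------------------------------------
# harmonisation


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ambiguous_band: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Merge exposure and outcome GWAS summaries onto shared, allele-aligned SNPs.

    Outcome records whose alleles are swapped relative to the exposure have
    ``beta_outcome`` negated (and eaf reflected); records matching only after
    strand complementation are aligned likewise.  Palindromic (A/T, C/G) SNPs
    are dropped unless effect-allele frequencies on both sides fall outside
    ``ambiguous_band`` and jointly identify the orientation.  Allele pairs
    that cannot be reconciled are dropped with a logged count.
    """
    for df, side in ((exposure, "exposure"), (outcome, "outcome")):
        need = {"snp", "effect_allele", "other_allele"}
        if not need <= set(df.columns):
            raise ValueError(f"{side} table lacks allele columns {sorted(need)}")
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    shared = exp.index.intersection(out.index)
    rows, n_dropped = [], 0
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_x, oa_x = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        ea_y, oa_y = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        flip = None  # None => unresolvable
        if _is_palindromic(ea_x, oa_x):
            flip = _palindromic_orientation(e, o, ea_x, oa_x, ambiguous_band)
        elif (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        else:
            comp = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
            if comp == (ea_x, oa_x):
                flip = False
            elif comp == (oa_x, ea_x):
                flip = True
        if flip is None:
            n_dropped += 1
            continue
        sign = -1.0 if flip else 1.0
        row = {
            "snp": snp,
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "beta_exposure": float(e["beta_exposure"]),
            "se_exposure": float(e["se_exposure"]),
            "beta_outcome": sign * float(o["beta_outcome"]),
            "se_outcome": float(o["se_outcome"]),
        }
        if "eaf" in exposure.columns:
            row["eaf"] = float(e["eaf"])
        rows.append(row)
    if n_dropped:
        logger.warning("harmonise: dropped %d unresolvable/ambiguous SNP(s)", n_dropped)
    if not rows:
        raise ValueError("no SNPs survived harmonisation")
    return pd.DataFrame(rows)


def _palindromic_orientation(e, o, ea_x, oa_x, band) -> Optional[bool]:
    """Use eaf on both sides to orient a palindromic SNP; None if ambiguous."""
    if "eaf" not in e.index or "eaf" not in o.index:
        return None
    fx, fy = float(e["eaf"]), float(o["eaf"])
    lo, hi = band
    if lo <= fx <= hi or lo <= fy <= hi or np.isnan(fx) or np.isnan(fy):
        return None
    same = (fx < 0.5) == (fy < 0.5)
    return not same  # frequencies on opposite sides of 0.5 => flipped strand report


# ---------------------------------------------------------------------------
# estimators


def ivw(stats_df: pd.DataFrame) -> TwoSampleResult:
    """Inverse-variance-weighted estimate over per-SNP Wald ratios.

    beta = sum(w_j r_j) / sum(w_j) with r_j = beta_y/beta_x and first-order
    weights w_j = beta_x^2 / se_y^2 — identical to the zero-intercept WLS of
    beta_y on beta_x with weights 1/se_y^2.  Multiplicative random effects:
    the fixed-effect SE is scaled by max(1, sqrt(Q/(J-1))).
    """
    df = _validate(stats_df, 1, "ivw")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    w = bx**2 / sy**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    j = len(df)
    scale = 1.0
    if j > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        scale = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * scale
    z = beta / se
    return TwoSampleResult(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_snps=j,
        metadata={"re_scale": scale, "weights": "first-order (beta_x^2/se_y^2)"},
    )


def mr_egger(stats_df: pd.DataFrame) -> TwoSampleResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas with intercept.

    SNPs are oriented so beta_exposure >= 0 before fitting (the conventional
    orientation making the intercept interpretable as average directional
    pleiotropy).  Weights 1/se_y^2; multiplicative random-effects dispersion
    estimated from the weighted residuals with J-2 degrees of freedom and
    t(J-2) reference — i.e. ordinary weighted-least-squares inference, which
    keeps the intercept (pleiotropy) test exactly calibrated under the null.
    Unlike :func:`ivw`, the dispersion is not floored at the fixed-effect
    level; the realised scale is reported in the result metadata.
    """
    df = _validate(stats_df, 3, "mr_egger")
    sign = np.sign(df["beta_exposure"].to_numpy(dtype=float))
    bx = df["beta_exposure"].to_numpy(dtype=float) * sign
    by = df["beta_outcome"].to_numpy(dtype=float) * sign
    sy = df["se_outcome"].to_numpy(dtype=float)
    if np.ptp(bx) < 1e-12 * max(1.0, np.abs(bx).max()):
        raise ValueError(
            "mr_egger unstable: no variation in instrument strength (all |beta_x| equal)"
        )
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    wx = x * w[:, None]
    xtx_inv = np.linalg.inv(x.T @ wx)
    coef = xtx_inv @ (wx.T @ by)
    resid = by - x @ coef
    j = len(df)
    q = float(np.sum(w * resid**2))
    # tiny floor only to keep SEs positive on exactly-collinear fixtures
    scale = max(np.sqrt(q / (j - 2)), 1e-12)
    cov = xtx_inv * scale**2
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icept, icept_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    tdist = stats.t(df=j - 2)
    p_slope = float(2 * tdist.sf(abs(slope / slope_se)))
    p_icept = float(2 * tdist.sf(abs(icept / icept_se)))
    crit = float(tdist.ppf(0.975))
    return TwoSampleResult(
        method="egger",
        beta=slope,
        se=slope_se,
        ci_low=slope - crit * slope_se,
        ci_high=slope + crit * slope_se,
        p_value=p_slope,
        n_snps=j,
        egger_intercept=icept,
        intercept_se=icept_se,
        intercept_p=p_icept,
        metadata={"re_scale": scale},
    )


def _ratio_weights(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and first-order inverse-variance weights (delta method)."""
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    r = by / bx
    var_r = sy**2 / bx**2
    return r, 1.0 / var_r


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median using midpoint cumulative weights."""
    order = np.argsort(r)
    r, w = r[order], w[order]
    wn = w / w.sum()
    cum = np.cumsum(wn) - wn / 2.0
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _parametric_boot(df: pd.DataFrame, estimator, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    j = len(bx)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(j) * sx
        byb = by + rng.standard_normal(j) * sy
        bxb = np.where(bxb == 0, 1e-300, bxb)
        rb = byb / bxb
        wb = bxb**2 / sy**2
        est[b] = estimator(rb, wb)
    return float(np.std(est, ddof=1))


def weighted_median(
    stats_df: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> TwoSampleResult:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Consistent if valid instruments carry at least half the weight.  Weights
    are first-order inverse variances of the ratios; the estimate is the
    linear interpolation of the ordered ratios at cumulative weight 0.5.
    """
    df = _validate(stats_df, 3, "weighted_median")
    if n_boot < 100:
        logger.warning("weighted_median: n_boot=%d is small; SE will be noisy", n_boot)
    r, w = _ratio_weights(df)
    if not np.all(w > 0):
        raise ValueError("weighted_median: nonpositive weights")
    beta = _weighted_median(r, w)
    se = _parametric_boot(df, _weighted_median, n_boot, seed)
    z = beta / se
    return TwoSampleResult(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_snps=len(df),
        n_boot=n_boot,
    )


def _weighted_mode(r: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> tuple[float, float]:
    """Argmax of a weighted normal-kernel density over the ratios.

    Bandwidth: bandwidth_factor x 0.9 x weighted-SD(r) x J^(-1/5) (a weighted
    analogue of Silverman's rule).  Returns (estimate, bandwidth).  A zero
    spread degenerates to the weighted mean of the identical values.
    """
    wn = w / w.sum()
    mu = float(np.sum(wn * r))
    sd = float(np.sqrt(np.sum(wn * (r - mu) ** 2)))
    if sd == 0:
        return mu, 0.0
    h = bandwidth_factor * 0.9 * sd * len(r) ** (-1 / 5)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = np.sum(
        wn[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2), axis=1
    )
    best = dens == dens.max()
    cand = grid[best]
    return float(cand[np.argmin(np.abs(cand))]), float(h)  # ties -> smallest |estimate|


def weighted_mode(
    stats_df: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> TwoSampleResult:
    """Weighted mode of Wald ratios (kernel-density argmax) with bootstrap SE.

    Consistent when the largest weighted cluster of per-SNP ratios is formed
    by valid instruments.  No NOME penalty is applied to the weights.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    df = _validate(stats_df, 3, "weighted_mode")
    r, w = _ratio_weights(df)
    beta, h = _weighted_mode(r, w, bandwidth_factor)
    se = _parametric_boot(
        df, lambda rb, wb: _weighted_mode(rb, wb, bandwidth_factor)[0], n_boot, seed
    )
    z = beta / se
    return TwoSampleResult(
        method="weighted_mode",
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_snps=len(df),
        bandwidth=h,
        n_boot=n_boot,
    )


def run_all(
    stats_df: pd.DataFrame,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode"),
    seed: int = 0,
    n_boot: int = 1000,
) -> list[TwoSampleResult]:
    """Run a set of two-sample estimators on one harmonised summary table."""
    dispatch = {
        "ivw": lambda d: ivw(d),
        "egger": lambda d: mr_egger(d),
        "weighted_median": lambda d: weighted_median(d, n_boot=n_boot, seed=seed),
        "weighted_mode": lambda d: weighted_mode(d, n_boot=n_boot, seed=seed + 1),
    }
    out = []
    for m in methods:
        if m not in dispatch:
            raise ValueError(f"unknown method '{m}'")
        out.append(dispatch[m](stats_df))
    return out
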