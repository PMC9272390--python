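"""One-sample Mendelian randomization by two-stage least squares.

Implements the individual-level instrumental-variable estimators used to
separate total from direct adiposity effects:

* univariable 2SLS (one exposure, its genetic risk score as instrument),
* multivariable 2SLS (both exposures instrumented jointly by both scores,
  yielding direct effects with mutual adjustment),
* a logistic second stage for binary outcomes such as statin use,
* product-term interaction tests of genetically predicted exposure with an
  observed modifier (sex, statin use, age),
* classical first-stage F and the Sanderson-Windmeijer conditional F for
  instrument strength in the multivariable design.

Second-stage standard errors for linear models are heteroskedasticity-robust
(HC1) sandwich estimates built on the proper IV influence form: coefficients
come from the projected design, residuals from the *observed* exposures, so
first-stage estimation uncertainty is carried by the sandwich.  Wald (normal)
reference is used for coefficient p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COVARIATES: tuple[str, ...] = ("sex", "age") + tuple(
    f"pc{i}" for i in range(1, 11)
)

#: condition-number threshold above which a design is declared singular
CONDITION_NUMBER_LIMIT = 1e10


class SingularDesignError(np.linalg.LinAlgError):
    """Instruments/covariates are collinear beyond the condition-number limit."""


class IdentificationError(ValueError):
    """Fewer instruments than endogenous exposures."""


class ConvergenceError(RuntimeError):
    """Second-stage maximum likelihood failed (e.g. perfect separation)."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a one-sample MR model.

    ``exposures`` and ``instruments`` are column names in the analysis table
    and must be equal in number (just-identified by construction: each
    exposure contributes one risk score, and in the multivariable model each
    exposure is instrumented by *both* scores).
    """

    exposures: tuple[str, ...]
    instruments: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    second_stage: str = "linear"  # or "logistic"
    interaction_with: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.instruments) < len(self.exposures):
            raise IdentificationError(
                f"{len(self.exposures)} exposure(s) need >= as many instruments, "
                f"got {len(self.instruments)}"
            )
        overlap = set(self.exposures) & set(self.covariates)
        if overlap:
            raise ValueError(f"exposures also listed as covariates: {sorted(overlap)}")
        if self.second_stage not in ("linear", "logistic"):
            raise ValueError(f"unknown second stage '{self.second_stage}'")


@dataclass
class MRResult:
    """One estimate record from any MR (or comparison) model.

    ``beta`` is on the SD scale for linear second stages and is the log odds
    ratio for logistic ones (use :attr:`odds_ratio` for the OR scale).
    """

    model_kind: str
    exposure: str
    outcome: str
    stratum: str
    n: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    f_stat: Optional[float] = None
    f_stat_conditional: Optional[float] = None
    interaction_p: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "stratum": self.stratum,
            "n": self.n,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "f_stat": self.f_stat,
            "f_stat_conditional": self.f_stat_conditional,
            "interaction_p": self.interaction_p,
        }


# ---------------------------------------------------------------------------
# linear algebra core


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"column '{c}' not present in analysis table")
    sub = df[list(cols)].apply(pd.to_numeric)
    return sub.dropna()


def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    n = len(df)
    return np.column_stack([df[c].to_numpy(dtype=float) for c in cols] + [np.ones(n)])


def _check_condition(mat: np.ndarray, what: str) -> None:
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > CONDITION_NUMBER_LIMIT:
        raise SingularDesignError(
            f"{what} is numerically singular (condition number {cond:.3g} "
            f"> {CONDITION_NUMBER_LIMIT:.0e})"
        )


def _project(z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Orthogonal projection of the columns of x onto the column space of z."""
    q, r = np.linalg.qr(z)
    return q @ (q.T @ x)


def iv_fit(
    y: np.ndarray,
    x_endog: np.ndarray,
    z_excl: np.ndarray,
    covars: np.ndarray,
    robust: str = "HC1",
) -> dict:
    """Two-stage least squares with a heteroskedasticity-robust IV sandwich.

    Parameters are raw column blocks: endogenous exposures ``x_endog``
    (n x p), excluded instruments ``z_excl`` (n x L, L >= p), and exogenous
    covariates ``covars`` (n x k, should include the intercept column).

    Returns coefficients for the full second-stage design ``[x_endog | covars]``
    and their covariance.  With ``robust="HC1"`` the variance is the sandwich

        (Xh'Xh)^-1 (sum_i u_i^2 xh_i xh_i') (Xh'Xh)^-1 * n/(n-k)

    with Xh the projected design and u the residuals computed from the
    *observed* exposures (the standard IV influence form).  ``robust="classical"``
    gives the homoskedastic IV variance  s^2 (Xh'Xh)^-1.
    """
    n = len(y)
    p = x_endog.shape[1]
    if z_excl.shape[1] < p:
        raise IdentificationError(
            f"{p} endogenous regressor(s) but only {z_excl.shape[1]} instrument(s)"
        )
    x_full = np.hstack([x_endog, covars])
    z_full = np.hstack([z_excl, covars])
    k = x_full.shape[1]
    if n < k + 1:
        raise ValueError(f"n={n} too small for {k} parameters")
    _check_condition(z_full, "instrument design")
    xh = np.hstack([_project(z_full, x_endog), covars])
    xtx = xh.T @ xh
    _check_condition(xtx, "projected second-stage design")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (xh.T @ y)
    resid = y - x_full @ beta
    if robust == "HC1":
        meat = (xh * resid[:, None] ** 2).T @ xh
        cov = xtx_inv @ meat @ xtx_inv * (n / (n - k))
    elif robust == "classical":
        s2 = float(resid @ resid) / (n - k)
        cov = s2 * xtx_inv
    else:
        raise ValueError(f"unknown robust flavour '{robust}'")
    return {"beta": beta, "cov": cov, "resid": resid, "n": n, "k": k, "xhat": xh}


def first_stage_f(
    x: np.ndarray, z_excl: np.ndarray, covars: np.ndarray
) -> float:
    """Classical joint F of the excluded instruments in the first-stage OLS.

    Compares x ~ covars against x ~ instruments + covars.
    """
    n = len(x)
    k_i = z_excl.shape[1]
    full = np.hstack([z_excl, covars])
    b_full, rss_full = _ols_rss(full, x)
    _, rss_restr = _ols_rss(covars, x)
    dof = n - full.shape[1]
    if rss_full <= 0:
        return np.inf
    return float(((rss_restr - rss_full) / k_i) / (rss_full / dof))


def _ols_rss(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _result_from_fit(
    fit: dict,
    idx: int,
    model_kind: str,
    exposure: str,
    outcome: str,
    stratum: str,
    **extra,
) -> MRResult:
    beta = float(fit["beta"][idx])
    se = float(np.sqrt(fit["cov"][idx, idx]))
    z = beta / se
    return MRResult(
        model_kind=model_kind,
        exposure=exposure,
        outcome=outcome,
        stratum=stratum,
        n=fit["n"],
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        **extra,
    )


# ---------------------------------------------------------------------------
# public fitting surface


def fit_2sls(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    stratum: str = "all",
    robust: str = "HC1",
) -> MRResult:
    """Univariable 2SLS: total effect of one exposure on one outcome.

    Stage 1 regresses the exposure on its score and covariates; stage 2
    regresses the outcome on the predicted exposure and the same covariates.
    Rows with any missing model variable are dropped (per-model complete
    cases), and the analysed n is reported on the result.
    """
    if len(spec.exposures) != 1:
        raise ValueError("fit_2sls takes exactly one exposure; use fit_mv_2sls")
    cols = [spec.outcome, *spec.exposures, *spec.instruments, *spec.covariates]
    data = _complete_cases(cohort, cols)
    y = data[spec.outcome].to_numpy(dtype=float)
    x = data[list(spec.exposures)].to_numpy(dtype=float)
    z = data[list(spec.instruments)].to_numpy(dtype=float)
    c = _design(data, spec.covariates)
    fit = iv_fit(y, x, z, c, robust=robust)
    f = first_stage_f(x[:, 0], z, c)
    return _result_from_fit(
        fit, 0, "uv-2sls", spec.exposures[0], spec.outcome, stratum, f_stat=f,
        metadata={"robust": robust},
    )


def fit_mv_2sls(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    stratum: str = "all",
    robust: str = "HC1",
) -> tuple[MRResult, MRResult]:
    """Multivariable 2SLS: direct effects of two exposures, mutually adjusted.

    Each exposure is regressed on *both* scores plus covariates in stage 1;
    stage 2 regresses the outcome on both predicted exposures plus covariates.
    Returns one result per exposure, each carrying its unconditional
    first-stage F and the Sanderson-Windmeijer conditional F.
    """
    if len(spec.exposures) != 2 or len(spec.instruments) != 2:
        raise ValueError("fit_mv_2sls requires two exposures and two instruments")
    cols = [spec.outcome, *spec.exposures, *spec.instruments, *spec.covariates]
    data = _complete_cases(cohort, cols)
    y = data[spec.outcome].to_numpy(dtype=float)
    x = data[list(spec.exposures)].to_numpy(dtype=float)
    z = data[list(spec.instruments)].to_numpy(dtype=float)
    c = _design(data, spec.covariates)
    fit = iv_fit(y, x, z, c, robust=robust)
    f_cond = _conditional_f_arrays(x, z, c)
    out = []
    for i, exposure in enumerate(spec.exposures):
        f_unc = first_stage_f(x[:, i], z[:, [i]], c)
        out.append(
            _result_from_fit(
                fit, i, "mv-2sls", exposure, spec.outcome, stratum,
                f_stat=f_unc, f_stat_conditional=f_cond[i],
                metadata={"robust": robust, "sw_df_scale": 2.0},
            )
        )
    return tuple(out)


def fit_2sls_logistic(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    stratum: str = "all",
    n_boot: int = 0,
    seed: int = 0,
) -> MRResult | tuple[MRResult, MRResult]:
    """2SLS with a maximum-likelihood logistic second stage for a binary outcome.

    Predicted exposure(s) from the linear first stage(s) are substituted into
    a logistic regression of the binary outcome on predicted exposures and
    covariates.  ``beta`` is the log odds ratio per unit of exposure.  Naive
    ML standard errors are reported by default (substitution SEs that ignore
    first-stage noise); pass ``n_boot`` > 0 for nonparametric-bootstrap SEs
    over both stages.
    """
    import statsmodels.api as sm

    cols = [spec.outcome, *spec.exposures, *spec.instruments, *spec.covariates]
    data = _complete_cases(cohort, cols)
    y = data[spec.outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) != 2:
        raise ValueError(
            f"logistic second stage needs a 0/1 outcome with both classes present, "
            f"observed values {classes[:4]}"
        )
    x = data[list(spec.exposures)].to_numpy(dtype=float)
    z = data[list(spec.instruments)].to_numpy(dtype=float)
    c = _design(data, spec.covariates)
    p = x.shape[1]

    def _second_stage(xa, za, ca, ya):
        xhat = _project(np.hstack([za, ca]), xa)
        design = np.hstack([xhat, ca])
        try:
            res = sm.Logit(ya, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises several flavours here
            raise ConvergenceError(f"logistic second stage failed: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError("logistic second stage did not converge")
        return res

    res = _second_stage(x, z, c, y)
    betas = res.params[:p]
    ses = np.sqrt(np.diag(res.cov_params()))[:p]
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = np.empty((n_boot, p))
        for b in range(n_boot):
            ii = rng.integers(0, n, size=n)
            try:
                rb = _second_stage(x[ii], z[ii], c[ii], y[ii])
                draws[b] = rb.params[:p]
            except ConvergenceError:
                draws[b] = np.nan
        ses = np.nanstd(draws, axis=0, ddof=1)

    kind = "uv-2sls-logistic" if p == 1 else "mv-2sls-logistic"
    results = []
    for i, exposure in enumerate(spec.exposures):
        beta, se = float(betas[i]), float(ses[i])
        zval = beta / se
        results.append(
            MRResult(
                model_kind=kind,
                exposure=exposure,
                outcome=spec.outcome,
                stratum=stratum,
                n=len(y),
                beta=beta,
                se=se,
                ci_low=beta - 1.96 * se,
                ci_high=beta + 1.96 * se,
                p_value=float(2 * stats.norm.sf(abs(zval))),
                f_stat=first_stage_f(x[:, i], z if p > 1 else z[:, [i]], c),
                metadata={"scale": "log-odds", "bootstrap": n_boot},
            )
        )
    return results[0] if p == 1 else tuple(results)


def interaction_test(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    modifier: str,
    stratum: str = "all",
    robust: str = "HC1",
) -> MRResult:
    """Product-term interaction of genetically predicted exposure with a modifier.

    The second stage is augmented with the observed modifier and the product
    (predicted exposure x modifier); the returned ``beta`` is the product-term
    coefficient with its robust SE and ``interaction_p``.  The modifier must
    vary within the analysis sample.
    """
    if len(spec.exposures) != 1:
        raise ValueError("interaction_test operates on a univariable spec")
    cols = [spec.outcome, *spec.exposures, *spec.instruments, modifier, *spec.covariates]
    data = _complete_cases(cohort, cols)
    m = data[modifier].to_numpy(dtype=float)
    if np.ptp(m) == 0:
        raise ValueError(f"modifier '{modifier}' is constant within the analysis sample")
    y = data[spec.outcome].to_numpy(dtype=float)
    x = data[list(spec.exposures)].to_numpy(dtype=float)
    z = data[list(spec.instruments)].to_numpy(dtype=float)
    covars = [c for c in spec.covariates if c != modifier]
    c = _design(data, covars)
    xhat = _project(np.hstack([z, c]), x)
    design = np.hstack([xhat, m[:, None], xhat * m[:, None], c])
    n, k = design.shape
    _check_condition(design.T @ design, "interaction design")
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ (design.T @ y)
    # residuals from the observed-exposure analogue of the augmented design
    x_obs = np.hstack([x, m[:, None], x * m[:, None], c])
    resid = y - x_obs @ beta
    if robust == "HC1":
        meat = (design * resid[:, None] ** 2).T @ design
        cov = xtx_inv @ meat @ xtx_inv * (n / (n - k))
    else:
        s2 = float(resid @ resid) / (n - k)
        cov = s2 * xtx_inv
    j = 2  # index of the product term: [xhat, m, xhat*m, covars]
    b = float(beta[j])
    se = float(np.sqrt(cov[j, j]))
    zval = b / se
    pval = float(2 * stats.norm.sf(abs(zval)))
    return MRResult(
        model_kind="interaction",
        exposure=spec.exposures[0],
        outcome=spec.outcome,
        stratum=stratum,
        n=n,
        beta=b,
        se=se,
        ci_low=b - 1.96 * se,
        ci_high=b + 1.96 * se,
        p_value=pval,
        interaction_p=pval,
        metadata={"modifier": modifier, "main_effect": float(beta[0])},
    )


# ---------------------------------------------------------------------------
# instrument strength


def _residualise(v: np.ndarray, covars: np.ndarray) -> np.ndarray:
    return v - _project(covars, v if v.ndim == 2 else v[:, None]).reshape(v.shape)


def _conditional_f_arrays(x: np.ndarray, z: np.ndarray, covars: np.ndarray) -> list[float]:
    """Sanderson-Windmeijer conditional F for each of two exposures.

    For exposure X1 given X2: (i) residualise X1, X2 and both instruments on
    the covariates; (ii) estimate X1 = delta * X2 by IV using both
    instruments; (iii) regress the residual X1 - delta_hat * X2 on both
    instruments; (iv) take the joint F of the instruments scaled by
    k_Z / (k_Z - k_other) = 2 for the 2-instrument, 1-other-exposure case.
    """
    n, p = x.shape
    if p != 2 or z.shape[1] != 2:
        raise IdentificationError("conditional F implemented for the 2x2 design")
    xr = _residualise(x, covars)
    zr = _residualise(z, covars)
    k_z = zr.shape[1]
    scale = k_z / (k_z - (p - 1))
    ones = np.ones((n, 1))
    out = []
    for i in range(p):
        x1 = xr[:, i]
        x2 = xr[:, [1 - i]]
        fit = iv_fit(x1, x2, zr, ones, robust="classical")
        delta = fit["beta"][0]
        resid = x1 - x2[:, 0] * delta
        # perfectly collinear exposures leave no instrumentable variation
        if resid @ resid <= 1e-10 * (x1 @ x1 + 1e-30):
            out.append(0.0)
            continue
        f_joint = first_stage_f(resid, zr, ones)
        out.append(float(f_joint * scale))
    return out


def conditional_f(cohort: pd.DataFrame, spec: ModelSpec) -> dict[str, dict[str, float]]:
    """Instrument-strength statistics for a model specification.

    For a univariable spec, returns the classical first-stage F of the score.
    For the multivariable (2 exposures, 2 scores) spec, returns both the
    unconditional F of each exposure on its own score and the
    Sanderson-Windmeijer conditional F given the other exposure.  Values far
    above 10 indicate negligible weak-instrument bias.
    """
    cols = [*spec.exposures, *spec.instruments, *spec.covariates]
    data = _complete_cases(cohort, cols)
    x = data[list(spec.exposures)].to_numpy(dtype=float)
    z = data[list(spec.instruments)].to_numpy(dtype=float)
    c = _design(data, spec.covariates)
    if len(spec.exposures) == 1:
        return {
            spec.exposures[0]: {
                "f_stat": first_stage_f(x[:, 0], z, c),
                "f_stat_conditional": None,
            }
        }
    if len(spec.instruments) < len(spec.exposures):
        raise IdentificationError("fewer instruments than exposures")
    f_cond = _conditional_f_arrays(x, z, c)
    out = {}
    for i, exposure in enumerate(spec.exposures):
        out[exposure] = {
            "f_stat": first_stage_f(x[:, i], z[:, [i]], c),
            "f_stat_conditional": f_cond[i],
        }
    return out
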