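"""Analysis-grid orchestration: total vs direct effects across strata.

Runs the full estimate grid — univariable (total) and multivariable (direct)
MR, conventional observational comparators, and the sex / statin-exclusion /
age-tertile stratifications — and emits long-format results tables shaped
like the study's supplementary tables.

Exposures and outcomes are z-standardised among sexes combined *before* any
stratification, so stratum-specific estimates stay on the whole-cohort SD
scale.  Any failing cell is logged and skipped; the grid never aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import onesample
from .genetics import standardise
from .onesample import ModelSpec, MRResult

logger = logging.getLogger(__name__)

SEX_LABELS = {0: "male", 1: "female"}

MR_MODEL_KINDS = ("uv-2sls", "mv-2sls")
OBS_MODEL_KINDS = ("obs-uv", "obs-mv")

#: covariates of the conventional (non-instrumented) models; socio-behavioural
#: adjustments exist only here, mirroring the observational design
OBS_COVARIATES = ("sex", "age", "education", "smoking", "alcohol")


@dataclass(frozen=True)
class StratumSpec:
    """A stratification rule.

    kind: one of all | by_sex | exclude_statin | age_tertile | sex_by_age_tertile.
    ``tertile_bounds`` may supply explicit age cut points; otherwise empirical
    1/3 and 2/3 quantiles are used.  Individuals whose age equals a boundary
    go to the lower tertile.
    """

    kind: str = "all"
    tertile_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        valid = {"all", "by_sex", "exclude_statin", "age_tertile", "sex_by_age_tertile"}
        if self.kind not in valid:
            raise ValueError(f"unknown stratum kind '{self.kind}'")


@dataclass
class AnalysisGrid:
    """The full model x outcome x stratum grid to evaluate."""

    exposures: tuple[str, str] = ("bmi", "whr")
    instruments: dict = field(default_factory=lambda: {"bmi": "grs_bmi", "whr": "grs_whr"})
    outcomes: tuple[str, ...] = ("trig", "ldl", "glyca")
    model_kinds: tuple[str, ...] = ("uv-2sls", "mv-2sls")
    strata: tuple[StratumSpec, ...] = (StratumSpec("all"),)
    covariates: tuple[str, ...] = onesample.DEFAULT_COVARIATES
    min_stratum_n: int = 50

    def instrument_of(self, exposure: str) -> str:
        return self.instruments[exposure]


def attach_scores(cohort, standardised: bool = True) -> pd.DataFrame:
    """Phenotype table with per-exposure genetic risk scores as grs_<exposure> columns.

    Scores are built from the cohort's own SNP-weights tables and (by default)
    z-standardised, ready for use as instruments.
    """
    from .genetics import build_grs

    ph = cohort.phenotypes.copy()
    for exposure, wdf in cohort.weights.items():
        rs = build_grs(cohort.genotypes, wdf)
        s = rs.to_series(f"grs_{exposure}")
        ph[f"grs_{exposure}"] = (standardise(s) if standardised else s).to_numpy()
    return ph


def age_tertiles(
    age: pd.Series, bounds: Optional[tuple[float, float]] = None
) -> tuple[pd.Series, tuple[float, float]]:
    """Assign age tertile labels 0/1/2 (boundary ages go to the lower tertile)."""
    if age.nunique() < 3:
        raise ValueError("need >= 3 distinct ages to form tertiles")
    if bounds is None:
        q1, q2 = age.quantile([1 / 3, 2 / 3]).to_numpy()
    else:
        q1, q2 = bounds
    lab = pd.Series(np.where(age <= q1, 0, np.where(age <= q2, 1, 2)), index=age.index)
    return lab, (float(q1), float(q2))


def standardise_for_analysis(
    cohort: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """z-standardise the named columns among sexes combined (pre-stratification)."""
    out = cohort.copy()
    for col in columns:
        out[col] = standardise(out[col], name=col)
    return out


def iter_strata(cohort: pd.DataFrame, spec: StratumSpec):
    """Yield (label, sub-table) pairs for one stratification rule."""
    if spec.kind == "all":
        yield "all", cohort
    elif spec.kind == "by_sex":
        for code, label in SEX_LABELS.items():
            yield label, cohort[cohort["sex"] == code]
    elif spec.kind == "exclude_statin":
        yield "statin-free", cohort[cohort["statin"] == 0]
    elif spec.kind == "age_tertile":
        lab, _ = age_tertiles(cohort["age"], spec.tertile_bounds)
        for t, name in enumerate(("age-t1", "age-t2", "age-t3")):
            yield name, cohort[lab == t]
    elif spec.kind == "sex_by_age_tertile":
        for code, sex_label in SEX_LABELS.items():
            sub = cohort[cohort["sex"] == code]
            lab, _ = age_tertiles(sub["age"], spec.tertile_bounds)
            for t in range(3):
                yield f"{sex_label}-age-t{t + 1}", sub[lab == t]


def _mr_covariates(grid: AnalysisGrid, stratum_label: str) -> tuple[str, ...]:
    # sex cannot be a covariate inside a single-sex stratum
    if stratum_label.startswith(("male", "female")):
        return tuple(c for c in grid.covariates if c != "sex")
    return grid.covariates


def run_grid(
    cohort: pd.DataFrame,
    grid: AnalysisGrid,
    pre_standardised: bool = False,
) -> pd.DataFrame:
    """Evaluate every MR (model, exposure, outcome, stratum) cell of the grid.

    Returns a long-format results table; failed or too-small cells are logged
    and skipped (tracked in the ``skips`` attribute of the returned frame).
    """
    if not pre_standardised:
        cols = [*grid.exposures, *grid.outcomes]
        cohort = standardise_for_analysis(cohort, cols)
    rows: list[dict] = []
    skips: list[str] = []

    for stratum_spec in grid.strata:
        for label, sub in iter_strata(cohort, stratum_spec):
            if len(sub) < grid.min_stratum_n:
                msg = f"stratum '{label}' too small (n={len(sub)})"
                logger.warning("skip: %s", msg)
                skips.extend(
                    f"{mk}/{e}/{o}/{label}"
                    for mk in grid.model_kinds
                    for e in grid.exposures
                    for o in grid.outcomes
                    if mk in MR_MODEL_KINDS
                )
                continue
            covars = _mr_covariates(grid, label)
            for outcome in grid.outcomes:
                for kind in grid.model_kinds:
                    if kind == "uv-2sls":
                        for exposure in grid.exposures:
                            spec = ModelSpec(
                                exposures=(exposure,),
                                instruments=(grid.instrument_of(exposure),),
                                outcome=outcome,
                                covariates=covars,
                            )
                            _try_cell(
                                rows, skips, f"uv-2sls/{exposure}/{outcome}/{label}",
                                lambda: onesample.fit_2sls(sub, spec, stratum=label),
                            )
                    elif kind == "mv-2sls":
                        spec = ModelSpec(
                            exposures=grid.exposures,
                            instruments=tuple(
                                grid.instrument_of(e) for e in grid.exposures
                            ),
                            outcome=outcome,
                            covariates=covars,
                        )
                        _try_cell(
                            rows, skips, f"mv-2sls/*/{outcome}/{label}",
                            lambda: onesample.fit_mv_2sls(sub, spec, stratum=label),
                        )
                    elif kind in OBS_MODEL_KINDS:
                        continue  # handled by conventional_models
                    else:
                        raise ValueError(f"unknown model kind '{kind}'")

    result = pd.DataFrame([r for r in rows])
    result.attrs["skips"] = skips
    return result


def _try_cell(rows: list, skips: list, cell: str, fit) -> None:
    try:
        res = fit()
    except Exception as exc:
        logger.warning("skip cell %s: %s", cell, exc)
        skips.append(cell)
        return
    if isinstance(res, MRResult):
        rows.append(res.to_dict())
    else:
        rows.extend(r.to_dict() for r in res)


def conventional_models(
    cohort: pd.DataFrame,
    grid: AnalysisGrid,
    pre_standardised: bool = False,
) -> pd.DataFrame:
    """Ordinary (non-instrumented) robust-SE regressions for comparison with MR.

    Each outcome is regressed on the measured exposure plus socio-behavioural
    covariates, without ("obs-uv", association analogue of the total effect)
    and with ("obs-mv") the other adiposity measure.  Output schema matches
    the MR rows with model_kind flagged obs-*.
    """
    import statsmodels.api as sm

    if not pre_standardised:
        cohort = standardise_for_analysis(
            cohort, [*grid.exposures, *grid.outcomes]
        )
    rows = []
    skips: list[str] = []
    for stratum_spec in grid.strata:
        for label, sub in iter_strata(cohort, stratum_spec):
            if len(sub) < grid.min_stratum_n:
                continue
            covars = [c for c in OBS_COVARIATES if c in sub.columns]
            if label.startswith(("male", "female")):
                covars = [c for c in covars if c != "sex"]
            for outcome in grid.outcomes:
                for exposure in grid.exposures:
                    other = [e for e in grid.exposures if e != exposure]
                    for kind, extra in (("obs-uv", []), ("obs-mv", other)):
                        cols = [outcome, exposure, *extra, *covars]
                        data = sub[cols].apply(pd.to_numeric).dropna()
                        if len(data) < grid.min_stratum_n:
                            skips.append(f"{kind}/{exposure}/{outcome}/{label}")
                            continue
                        design = sm.add_constant(data[[exposure, *extra, *covars]])
                        try:
                            fit = sm.OLS(data[outcome], design).fit(cov_type="HC1")
                        except Exception as exc:
                            logger.warning(
                                "skip cell %s/%s/%s/%s: %s",
                                kind, exposure, outcome, label, exc,
                            )
                            skips.append(f"{kind}/{exposure}/{outcome}/{label}")
                            continue
                        b = float(fit.params[exposure])
                        se = float(fit.bse[exposure])
                        rows.append(
                            {
                                "model_kind": kind,
                                "exposure": exposure,
                                "outcome": outcome,
                                "stratum": label,
                                "n": int(fit.nobs),
                                "beta": b,
                                "se": se,
                                "ci_low": b - 1.96 * se,
                                "ci_high": b + 1.96 * se,
                                "p": float(fit.pvalues[exposure]),
                                "f_stat": None,
                                "f_stat_conditional": None,
                                "interaction_p": None,
                            }
                        )
    result = pd.DataFrame(rows)
    result.attrs["skips"] = skips
    return result


def statin_exclusion_analysis(
    cohort: pd.DataFrame,
    grid: AnalysisGrid,
    truth=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the MR grid among statin non-users, with a collider-bias report.

    Statin use is caused by the exposures and by latent LDL-C, so the
    statin-free subset is selected on a collider and stratified estimates can
    be biased.  The report compares each statin-free direct/total estimate
    against (a) the generative coefficient when a truth record is supplied
    and (b) the all-sample estimate on the latent (pre-treatment) outcome
    when a ``<outcome>_latent`` column exists.
    """
    cols = [*grid.exposures, *grid.outcomes]
    latent_cols = [f"{o}_latent" for o in grid.outcomes if f"{o}_latent" in cohort.columns]
    std = standardise_for_analysis(cohort, cols)
    for lc in latent_cols:  # latent outcomes standardised on their own scale
        std[lc] = standardise(std[lc], name=lc)

    if (cohort["statin"] == 1).sum() == 0:
        logger.warning(
            "statin prevalence is 0: statin-free analysis equals the main analysis"
        )

    main_grid = replace_strata(grid, (StratumSpec("all"),))
    excl_grid = replace_strata(grid, (StratumSpec("exclude_statin"),))
    excl = run_grid(std, excl_grid, pre_standardised=True)

    # all-sample reference on latent outcomes (treatment-free counterfactual)
    latent_grid = AnalysisGrid(
        exposures=grid.exposures,
        instruments=grid.instruments,
        outcomes=tuple(latent_cols),
        model_kinds=grid.model_kinds,
        strata=(StratumSpec("all"),),
        covariates=grid.covariates,
        min_stratum_n=grid.min_stratum_n,
    )
    latent_res = (
        run_grid(std, latent_grid, pre_standardised=True)
        if latent_cols
        else pd.DataFrame()
    )

    report_rows = []
    for _, row in excl.iterrows():
        rec = {
            "model_kind": row["model_kind"],
            "exposure": row["exposure"],
            "outcome": row["outcome"],
            "beta_statin_free": row["beta"],
            "se_statin_free": row["se"],
        }
        if truth is not None:
            cfg = truth.config
            if row["model_kind"] == "mv-2sls":
                rec["truth"] = {
                    "bmi": cfg.theta_bmi, "whr": cfg.theta_whr
                }[row["exposure"]].get(row["outcome"])
            elif row["model_kind"] == "uv-2sls":
                fn = {
                    "bmi": cfg.total_effect_bmi, "whr": cfg.total_effect_whr
                }[row["exposure"]]
                rec["truth"] = fn(row["outcome"]) if row["outcome"] in cfg.outcomes else None
            if rec.get("truth") is not None:
                rec["bias_vs_truth"] = row["beta"] - rec["truth"]
        if len(latent_res):
            match = latent_res[
                (latent_res["model_kind"] == row["model_kind"])
                & (latent_res["exposure"] == row["exposure"])
                & (latent_res["outcome"] == f"{row['outcome']}_latent")
            ]
            if len(match) == 1:
                rec["beta_all_sample_latent"] = float(match["beta"].iloc[0])
                rec["bias_vs_latent"] = row["beta"] - rec["beta_all_sample_latent"]
        report_rows.append(rec)
    return excl, pd.DataFrame(report_rows)


def replace_strata(grid: AnalysisGrid, strata: tuple[StratumSpec, ...]) -> AnalysisGrid:
    return AnalysisGrid(
        exposures=grid.exposures,
        instruments=grid.instruments,
        outcomes=grid.outcomes,
        model_kinds=grid.model_kinds,
        strata=strata,
        covariates=grid.covariates,
        min_stratum_n=grid.min_stratum_n,
    )


def age_stratified_analysis(
    cohort: pd.DataFrame,
    grid: AnalysisGrid,
    n_tertiles: int = 3,
    bounds: Optional[tuple[float, float]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the MR grid within age tertiles (age proxies medication exposure).

    Age is not caused by adiposity, so age stratification avoids the collider
    problem of conditioning on statin use directly, while still separating
    low- from high-medication strata.  Returns the per-tertile results plus a
    report of tertile boundaries, sizes and statin prevalence.
    """
    if n_tertiles != 3:
        raise ValueError("tertile stratification is defined for n_tertiles=3")
    labels, (q1, q2) = age_tertiles(cohort["age"], bounds)
    tert_grid = replace_strata(
        grid, (StratumSpec("age_tertile", tertile_bounds=(q1, q2)),)
    )
    results = run_grid(cohort, tert_grid)
    report = []
    for t, name in enumerate(("age-t1", "age-t2", "age-t3")):
        sub = cohort[labels == t]
        report.append(
            {
                "stratum": name,
                "age_min": float(sub["age"].min()),
                "age_max": float(sub["age"].max()),
                "n": len(sub),
                "statin_prevalence": float(sub["statin"].mean())
                if "statin" in sub.columns
                else np.nan,
            }
        )
    return results, pd.DataFrame(report)
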