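"""Individual-level 2SLS: closed forms, sandwich oracle, recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from adipomr import pipeline, simulate
from adipomr.onesample import (
    DEFAULT_COVARIATES,
    IdentificationError,
    ModelSpec,
    SingularDesignError,
    conditional_f,
    fit_2sls,
    fit_2sls_logistic,
    fit_mv_2sls,
    first_stage_f,
    interaction_test,
)


def _toy_cohort(rng, n=500, beta=0.5):
    z = rng.integers(0, 3, size=n).astype(float)
    u = rng.normal(size=n)
    x = 0.4 * z + u + rng.normal(size=n)
    y = beta * x + u + rng.normal(size=n)
    return pd.DataFrame({"z": z, "x": x, "y": y})


class TestUnivariable2sls:
    def test_outcome_identical_to_exposure_gives_unit_beta(self, rng):
        df = _toy_cohort(rng)
        df["y"] = df["x"]
        res = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=()))
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.se < 1e-8

    def test_just_identified_equals_wald_ratio(self, rng):
        df = _toy_cohort(rng)
        res = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=()))
        wald = np.cov(df.z, df.y)[0, 1] / np.cov(df.z, df.x)[0, 1]
        assert res.beta == pytest.approx(wald, abs=1e-10)

    def test_beta_and_hc1_se_match_matrix_oracle(self, rng):
        """Independent explicit-projection oracle on a 200-row fixture."""
        n = 200
        df = _toy_cohort(rng, n=n)
        df["c1"] = rng.normal(size=n)
        df["c2"] = rng.normal(size=n)
        res = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=("c1", "c2")))

        zf = np.column_stack([df.z, df.c1, df.c2, np.ones(n)])
        xf = np.column_stack([df.x, df.c1, df.c2, np.ones(n)])
        y = df.y.to_numpy()
        p = zf @ np.linalg.inv(zf.T @ zf) @ zf.T
        xh = p @ xf
        a_inv = np.linalg.inv(xh.T @ xh)
        beta = a_inv @ xh.T @ y
        u = y - xf @ beta
        meat = sum(u[i] ** 2 * np.outer(xh[i], xh[i]) for i in range(n))
        cov = a_inv @ meat @ a_inv * n / (n - 4)
        assert res.beta == pytest.approx(beta[0], rel=1e-10)
        assert res.se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-8)

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        df = _toy_cohort(rng, n=300)
        base = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=()))
        # noise residualised against intercept, z, x, y => exactly orthogonal
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(len(df)), df.z, df.x, df.y])
        )
        w = rng.normal(size=len(df))
        df["w"] = w - q @ (q.T @ w)
        aug = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=("w",)))
        assert aug.beta == pytest.approx(base.beta, abs=1e-10)

    def test_scale_equivariance(self, rng):
        df = _toy_cohort(rng)
        spec = ModelSpec(("x",), ("z",), "y", covariates=())
        base = fit_2sls(df, spec)
        df2 = df.assign(y=3.0 * df.y)
        scaled = fit_2sls(df2, spec)
        assert scaled.beta == pytest.approx(3 * base.beta, rel=1e-10)
        assert scaled.se == pytest.approx(3 * base.se, rel=1e-10)
        df3 = df.assign(x=df.x / 2.0)
        assert fit_2sls(df3, spec).beta == pytest.approx(2 * base.beta, rel=1e-10)

    def test_missing_rows_dropped_per_model(self, rng):
        df = _toy_cohort(rng, n=400)
        df.loc[:49, "y"] = np.nan
        res = fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=()))
        assert res.n == 350

    def test_instrument_collinear_with_covariate_raises(self, rng):
        df = _toy_cohort(rng)
        df["zc"] = df["z"]
        with pytest.raises(SingularDesignError):
            fit_2sls(df, ModelSpec(("x",), ("z",), "y", covariates=("zc",)))


class TestMultivariable2sls:
    def test_direct_effect_recovery_on_preset(self, scored_phenotypes):
        mv = fit_mv_2sls(
            scored_phenotypes,
            ModelSpec(("bmi", "whr"), ("grs_bmi", "grs_whr"), "trig"),
        )
        by_exp = {r.exposure: r for r in mv}
        assert by_exp["bmi"].beta == pytest.approx(0.0, abs=3.5 * by_exp["bmi"].se)
        assert by_exp["whr"].beta == pytest.approx(0.6, abs=3.5 * by_exp["whr"].se)

    def test_univariable_total_effect_is_delta_times_theta(self, scored_phenotypes):
        uv = fit_2sls(
            scored_phenotypes, ModelSpec(("bmi",), ("grs_bmi",), "trig")
        )
        assert uv.beta == pytest.approx(0.24, abs=3.5 * uv.se)

    def test_duplicate_exposure_and_instrument_is_singular(self, rng):
        df = _toy_cohort(rng)
        df["x2"] = df["x"]
        with pytest.raises(SingularDesignError):
            fit_mv_2sls(df, ModelSpec(("x", "x2"), ("z", "z"), "y", covariates=()))

    def test_irrelevant_independent_second_exposure_reduces_to_univariable(self, rng):
        n = 20_000
        z1 = rng.binomial(2, 0.3, n).astype(float)
        z2 = rng.binomial(2, 0.3, n).astype(float)
        x1 = 0.3 * z1 + rng.normal(size=n)
        x2 = 0.3 * z2 + rng.normal(size=n)
        y = 0.5 * x1 + rng.normal(size=n)
        df = pd.DataFrame({"z1": z1, "z2": z2, "x1": x1, "x2": x2, "y": y})
        uv = fit_2sls(df, ModelSpec(("x1",), ("z1",), "y", covariates=()))
        mv = fit_mv_2sls(
            df, ModelSpec(("x1", "x2"), ("z1", "z2"), "y", covariates=())
        )
        assert mv[0].beta == pytest.approx(
            uv.beta, abs=2 * np.hypot(uv.se, mv[0].se)
        )


class TestLogisticSecondStage:
    def test_null_binary_outcome_gives_unit_or(self, rng):
        df = _toy_cohort(rng, n=5000)
        df["s"] = rng.binomial(1, 0.2, size=len(df))
        res = fit_2sls_logistic(df, ModelSpec(("x",), ("z",), "s", covariates=()))
        assert res.odds_ratio == pytest.approx(1.0, abs=3.5 * res.se)

    def test_all_zero_outcome_rejected(self, rng):
        df = _toy_cohort(rng)
        df["s"] = 0
        with pytest.raises(ValueError, match="both classes"):
            fit_2sls_logistic(df, ModelSpec(("x",), ("z",), "s", covariates=()))

    def test_recovers_large_n_oracle(self):
        """Estimate at n=50k agrees with the same estimator's large-n limit.

        The large-n oracle value was computed once with this generator at
        n=500_000 (seed 77): marginal log-OR of genetically predicted BMI on
        statin use, sexes combined, 0.428 (statin ORs are population-averaged
        and therefore attenuated relative to the conditional logit slope).
        """
        oracle_log_or = 0.428
        cfg = simulate.ukb_like_config(seed=21, n_individuals=50_000)
        ph = pipeline.attach_scores(simulate.simulate_cohort(cfg))
        ph = pipeline.standardise_for_analysis(ph, ["bmi", "whr"])
        res = fit_2sls_logistic(
            ph, ModelSpec(("bmi",), ("grs_bmi",), "statin")
        )
        assert res.beta == pytest.approx(oracle_log_or, abs=3.5 * res.se)


class TestInteraction:
    def test_constant_modifier_rejected(self, rng):
        df = _toy_cohort(rng)
        df["m"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            interaction_test(
                df, ModelSpec(("x",), ("z",), "y", covariates=()), "m"
            )

    def test_product_coefficient_invariant_to_modifier_shift(self, rng):
        df = _toy_cohort(rng, n=2000)
        df["m"] = rng.binomial(1, 0.5, size=len(df)).astype(float)
        spec = ModelSpec(("x",), ("z",), "y", covariates=())
        r0 = interaction_test(df, spec, "m")
        df["m"] = df["m"] + 5.0
        r1 = interaction_test(df, spec, "m")
        assert r1.beta == pytest.approx(r0.beta, rel=1e-8)
        # main effect at modifier=0 shifts by 5 * product coefficient
        assert r1.metadata["main_effect"] == pytest.approx(
            r0.metadata["main_effect"] - 5.0 * r0.beta, rel=1e-6, abs=1e-8
        )

    def test_recovers_sex_difference_in_effect(self):
        cfg = simulate.ukb_like_config(
            seed=31,
            n_individuals=30_000,
            sex_effect_overrides={"female": {"theta_bmi": {"trig": 0.3}}},
        )
        ph = pipeline.attach_scores(simulate.simulate_cohort(cfg))
        ph = pipeline.standardise_for_analysis(ph, ["bmi", "whr", "trig"])
        covs = tuple(c for c in DEFAULT_COVARIATES if c != "sex")
        res = interaction_test(
            ph, ModelSpec(("bmi",), ("grs_bmi",), "trig", covariates=covs), "sex"
        )
        assert res.beta == pytest.approx(0.3, abs=3.5 * res.se)
        assert res.interaction_p < 0.01


class TestInstrumentStrength:
    def test_conditional_equals_unconditional_when_independent(self):
        cfg = simulate.SimConfig(
            n_individuals=50_000, delta_bmi_to_whr=0.0, seed=41
        )
        ph = pipeline.attach_scores(simulate.simulate_cohort(cfg))
        out = conditional_f(
            ph, ModelSpec(("bmi", "whr"), ("grs_bmi", "grs_whr"), "trig")
        )
        for exp in ("bmi", "whr"):
            ratio = out[exp]["f_stat_conditional"] / out[exp]["f_stat"]
            assert ratio == pytest.approx(1.0, abs=0.10)

    def test_duplicate_exposure_gives_zero_conditional_f(self, rng):
        n = 2000
        z1 = rng.binomial(2, 0.3, n).astype(float)
        z2 = rng.binomial(2, 0.3, n).astype(float)
        x1 = 0.3 * z1 + 0.3 * z2 + rng.normal(size=n)
        df = pd.DataFrame({"z1": z1, "z2": z2, "x1": x1, "x2": x1, "y": rng.normal(size=n)})
        out = conditional_f(
            df, ModelSpec(("x1", "x2"), ("z1", "z2"), "y", covariates=())
        )
        assert out["x1"]["f_stat_conditional"] == pytest.approx(0.0, abs=1e-6)

    def test_underidentified_spec_rejected(self):
        with pytest.raises(IdentificationError):
            ModelSpec(("x1", "x2"), ("z1",), "y", covariates=())

    def test_univariable_spec_returns_classical_f(self, rng):
        df = _toy_cohort(rng, n=1000)
        out = conditional_f(df, ModelSpec(("x",), ("z",), "y", covariates=()))
        z = np.column_stack([df.z])
        c = np.ones((len(df), 1))
        assert out["x"]["f_stat"] == pytest.approx(
            first_stage_f(df.x.to_numpy(), z, c)
        )
        assert out["x"]["f_stat_conditional"] is None
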