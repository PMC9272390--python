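"""Summary-statistics MR: harmonisation and the four pleiotropy-model estimators."""

import numpy as np
import pandas as pd
import pytest

from adipomr.twosample import (
    harmonise,
    ivw,
    mr_egger,
    run_all,
    weighted_median,
    weighted_mode,
)
from conftest import make_sumstats


def _gwas(snps, ea, oa, beta, se=0.01, eaf=None):
    df = pd.DataFrame(
        {
            "snp": snps,
            "effect_allele": ea,
            "other_allele": oa,
            "beta_exposure": beta,
            "se_exposure": se,
            "beta_outcome": beta,
            "se_outcome": se,
        }
    )
    if eaf is not None:
        df["eaf"] = eaf
    return df


class TestHarmonise:
    def _pair(self, ea_y, oa_y, beta_y, eaf_x=None, eaf_y=None):
        exp = pd.DataFrame(
            {
                "snp": ["rs1"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "beta_exposure": [0.1],
                "se_exposure": [0.01],
            }
        )
        out = pd.DataFrame(
            {
                "snp": ["rs1"],
                "effect_allele": [ea_y],
                "other_allele": [oa_y],
                "beta_outcome": [beta_y],
                "se_outcome": [0.02],
            }
        )
        if eaf_x is not None:
            exp["eaf"] = eaf_x
            exp.loc[0, "effect_allele"], exp.loc[0, "other_allele"] = "A", "T"
        if eaf_y is not None:
            out["eaf"] = eaf_y
        return exp, out

    def test_identical_orientation_is_noop(self):
        exp, out = self._pair("A", "G", 0.3)
        h = harmonise(exp, out)
        assert h["beta_outcome"].iloc[0] == 0.3

    def test_swapped_alleles_negate_outcome_beta(self):
        exp, out = self._pair("G", "A", 0.3)
        h = harmonise(exp, out)
        assert h["beta_outcome"].iloc[0] == -0.3

    def test_strand_complement_resolved(self):
        exp, out = self._pair("T", "C", 0.3)  # complement of A/G
        assert harmonise(exp, out)["beta_outcome"].iloc[0] == 0.3
        exp, out = self._pair("C", "T", 0.3)  # complement of swapped
        assert harmonise(exp, out)["beta_outcome"].iloc[0] == -0.3

    @pytest.mark.parametrize(
        "eaf_y,expected_sign",
        [
            (0.11, +1),  # same minor side as eaf_x=0.10 => aligned
            (0.89, -1),  # opposite side => flipped strand report
        ],
    )
    def test_palindromic_oriented_by_eaf(self, eaf_y, expected_sign):
        exp, out = self._pair("A", "T", 0.3, eaf_x=0.10, eaf_y=eaf_y)
        h = harmonise(exp, out)
        assert h["beta_outcome"].iloc[0] == pytest.approx(expected_sign * 0.3)

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp, out = self._pair("A", "T", 0.3, eaf_x=0.50, eaf_y=0.10)
        with pytest.raises(ValueError, match="no SNPs survived"):
            harmonise(exp, out)

    def test_mismatched_allele_pair_dropped_with_count(self, caplog):
        exp1, out1 = self._pair("A", "G", 0.3)
        exp2, out2 = self._pair("A", "C", 0.5)
        exp2["snp"], out2["snp"] = "rs2", "rs2"
        exp = pd.concat([exp1, exp2], ignore_index=True)
        out = pd.concat([out1, out2], ignore_index=True)
        with caplog.at_level("WARNING"):
            h = harmonise(exp, out)
        assert list(h["snp"]) == ["rs1"]
        assert "dropped 1" in caplog.text


class TestIvw:
    def test_single_snp_is_wald_ratio(self):
        df = make_sumstats([0.2], [0.08])
        assert ivw(df).beta == pytest.approx(0.4, abs=1e-12)

    def test_constant_ratio_recovered_for_any_weights(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        df = make_sumstats(bx, 0.7 * bx, sy=rng.uniform(0.005, 0.05, 8))
        assert ivw(df).beta == pytest.approx(0.7, abs=1e-12)

    def test_matches_weighted_least_squares_oracle(self, rng):
        """Zero-intercept WLS (statsmodels) with weights 1/se_y^2."""
        import statsmodels.api as sm

        bx = rng.uniform(0.05, 0.3, 5)
        by = 0.4 * bx + rng.normal(0, 0.02, 5)
        sy = rng.uniform(0.01, 0.03, 5)
        df = make_sumstats(bx, by, sy=sy)
        res = ivw(df)
        wls = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert res.beta == pytest.approx(wls.params[0], abs=1e-10)
        # fixed-effect SE from the analytic weight sum, times the RE scale
        se_fixed = 1 / np.sqrt(np.sum(bx**2 / sy**2))
        assert res.se == pytest.approx(se_fixed * res.metadata["re_scale"], rel=1e-10)

    def test_zero_exposure_beta_excluded(self, caplog):
        df = make_sumstats([0.0, 0.2], [0.1, 0.1])
        with caplog.at_level("WARNING"):
            res = ivw(df)
        assert res.n_snps == 1
        assert res.beta == pytest.approx(0.5)


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self, rng):
        bx = np.linspace(0.05, 0.3, 6)
        df = make_sumstats(bx, 0.05 + 0.3 * bx)
        res = mr_egger(df)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.05, abs=1e-12)

    def test_balanced_pleiotropy_null_mean_intercept_zero(self):
        rng = np.random.default_rng(55)
        icepts = []
        for _ in range(500):
            bx = rng.uniform(0.05, 0.15, 20)
            by = 0.3 * bx + rng.normal(0, 0.01, 20)
            icepts.append(mr_egger(make_sumstats(bx, by)).egger_intercept)
        icepts = np.asarray(icepts)
        mc_se = icepts.std(ddof=1) / np.sqrt(len(icepts))
        assert abs(icepts.mean()) < 3 * mc_se

    def test_zero_intercept_constraint_reduces_to_ivw(self, rng):
        """Constrained-regression oracle: dropping the intercept recovers IVW."""
        import statsmodels.api as sm

        bx = rng.uniform(0.05, 0.3, 7)
        by = 0.4 * bx + rng.normal(0, 0.02, 7)
        sy = rng.uniform(0.01, 0.03, 7)
        df = make_sumstats(bx, by, sy=sy)
        constrained = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert ivw(df).beta == pytest.approx(constrained.params[0], abs=1e-10)

    def test_no_spread_in_instrument_strength_rejected(self):
        df = make_sumstats([0.1, 0.1, 0.1], [0.05, 0.04, 0.06])
        with pytest.raises(ValueError, match="unstable"):
            mr_egger(df)

    def test_orientation_flip_invariance(self, rng):
        bx = rng.uniform(0.05, 0.3, 9)
        by = 0.4 * bx + rng.normal(0, 0.01, 9)
        df = make_sumstats(bx, by)
        flipped = df.copy()
        flipped.loc[2, ["beta_exposure", "beta_outcome"]] *= -1
        a, b = mr_egger(df), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weight_odd_median_is_outlier_robust(self):
        df = make_sumstats([0.1, 0.1, 0.1], [0.1 * 1, 0.1 * 2, 0.1 * 9])
        res = weighted_median(df, n_boot=100, seed=0)
        assert res.beta == pytest.approx(2.0, abs=1e-10)

    def test_dominant_weight_pins_estimate(self):
        """Brute-force cumulative-weight oracle: one SNP holds nearly all weight.

        Under the midpoint-cumulative convention the 0.5 quantile falls next
        to the dominant SNP's ratio, so the interpolated estimate is pinned
        at that ratio up to the vanishing residual-weight interpolation term.
        """
        bx = np.array([1.0, 0.01, 0.01])
        by = np.array([1.0 * 0.7, 0.01 * 2.0, 0.01 * 3.0])
        sy = np.array([0.01, 0.01, 0.01])
        df = make_sumstats(bx, by, sy=sy)
        w = bx**2 / sy**2
        wn = w / w.sum()
        assert wn[0] > 0.999
        # independent brute-force oracle: midpoint cumulative weights + interp
        order = np.argsort(by / bx)
        r_s, w_s = (by / bx)[order], wn[order]
        cum = np.cumsum(w_s) - w_s / 2
        oracle = np.interp(0.5, cum, r_s)
        res = weighted_median(df, n_boot=100, seed=0)
        assert res.beta == pytest.approx(oracle, abs=1e-12)
        assert res.beta == pytest.approx(0.7, abs=1e-3)

    def test_contamination_bias_below_ivw(self):
        """30% pleiotropic SNPs (+1 offset): median mean bias < IVW mean bias."""
        rng = np.random.default_rng(66)
        bias_med, bias_ivw = [], []
        for _ in range(300):
            bx = rng.uniform(0.05, 0.15, 20)
            by = 0.3 * bx + rng.normal(0, 0.005, 20)
            by[:6] += 1.0 * bx[:6]  # directional pleiotropy on 30% of SNPs
            df = make_sumstats(bx, by, sy=0.005 * np.ones(20))
            bias_med.append(weighted_median(df, n_boot=100, seed=1).beta - 0.3)
            bias_ivw.append(ivw(df).beta - 0.3)
        assert abs(np.mean(bias_med)) < abs(np.mean(bias_ivw))

    def test_reordering_and_signflip_invariance(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        df = make_sumstats(bx, by)
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        flipped = df.copy()
        flipped.loc[4, ["beta_exposure", "beta_outcome"]] *= -1
        base = weighted_median(df, n_boot=100, seed=5).beta
        assert weighted_median(shuffled, n_boot=100, seed=5).beta == pytest.approx(base, abs=1e-9)
        assert weighted_median(flipped, n_boot=100, seed=5).beta == pytest.approx(base, abs=1e-9)


class TestWeightedMode:
    def test_point_mass_returns_exact_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        df = make_sumstats(bx, 0.35 * bx)
        res = weighted_mode(df, n_boot=100, seed=0)
        assert res.beta == pytest.approx(0.35, abs=1e-12)
        assert res.bandwidth == 0.0

    def test_cluster_beats_mean(self):
        ratios = np.array([0.3] * 7 + [2.0] * 3)
        bx = np.full(10, 0.1)
        df = make_sumstats(bx, ratios * bx)
        res = weighted_mode(df, n_boot=100, seed=0)
        assert res.beta == pytest.approx(0.3, abs=0.05)
        assert abs(res.beta - ratios.mean()) > 0.4  # not the mean (~0.81)

    def test_matches_grid_search_kde_oracle(self, rng):
        """Independent dense-grid weighted-KDE argmax with the same bandwidth rule."""
        bx = rng.uniform(0.05, 0.3, 12)
        by = 0.4 * bx + rng.normal(0, 0.02, 12)
        sy = rng.uniform(0.01, 0.03, 12)
        df = make_sumstats(bx, by, sy=sy)
        res = weighted_mode(df, n_boot=100, seed=0)

        r = by / bx
        w = bx**2 / sy**2
        wn = w / w.sum()
        mu = np.sum(wn * r)
        sd = np.sqrt(np.sum(wn * (r - mu) ** 2))
        h = 0.9 * sd * len(r) ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 20_001)
        dens = np.zeros_like(grid)
        for j in range(len(r)):
            dens += wn[j] * np.exp(-0.5 * ((grid - r[j]) / h) ** 2)
        oracle = grid[np.argmax(dens)]
        step = (grid[-1] - grid[0]) / 511  # implementation grid resolution
        assert res.beta == pytest.approx(oracle, abs=2 * step)

    def test_large_bandwidth_limit_approaches_weighted_mean(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.01, 0.03, 8)
        df = make_sumstats(bx, by, sy=sy)
        r = by / bx
        w = bx**2 / sy**2
        wmean = np.sum(w * r) / w.sum()
        res = weighted_mode(df, bandwidth_factor=30.0, n_boot=100, seed=0)
        # resolution limit of the 512-point argmax grid at this bandwidth
        span = (r.max() + 3 * res.bandwidth) - (r.min() - 3 * res.bandwidth)
        assert res.beta == pytest.approx(wmean, abs=2.5 * span / 511)


class TestNoPleiotropyConsensus:
    def test_all_four_estimators_unbiased_under_valid_instruments(self):
        rng = np.random.default_rng(77)
        sums = {m: [] for m in ("ivw", "egger", "weighted_median", "weighted_mode")}
        n_rep = 120
        for _ in range(n_rep):
            bx_true = rng.uniform(0.05, 0.15, 25)
            bx = bx_true + rng.normal(0, 0.004, 25)
            by = 0.3 * bx_true + rng.normal(0, 0.01, 25)
            df = make_sumstats(bx, by, sx=0.004 * np.ones(25), sy=0.01 * np.ones(25))
            for res in run_all(df, seed=int(rng.integers(2**31 - 1)), n_boot=100):
                sums[res.method].append(res.beta)
        for method, vals in sums.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - 0.3) < 4 * mc_se, method
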