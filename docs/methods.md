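# Methods

## Estimands and causal structure

The package targets two estimands per exposure–outcome pair, in SD units of
internally z-standardised variables (standardised among sexes combined,
before any stratification):

* **total effect** — univariable 2SLS of the outcome on one genetically
  predicted exposure;
* **direct effect** — multivariable 2SLS with both adiposity exposures
  instrumented jointly, i.e. the effect of each exposure not transmitted
  through the other.

The synthetic cohort is generated from the structural model

```
G_bmi, G_whr : polygenic scores, SNPs i.i.d. Binomial(2, f_j), no LD
U            : standard-normal confounder
BMI  = G_bmi + kappa_bmi * U + e_b
WHR  = G_whr + delta * BMI + kappa_whr * U + e_w
Y_k* = theta_bmi_k * BMI + theta_whr_k * WHR + kappa * U + e_k
S    ~ Bernoulli(expit(a + b_bmi BMI + b_whr WHR + b_ldl LDL* + g (age - 55.5)))
LDL  = LDL* - tau * S                       (measured LDL-C)
```

Residual variances are solved so every exposure and latent outcome has unit
population variance; a configuration whose implied residual variance is
non-positive is rejected with the offending parameter named. Under the
default (disjoint instrument sets), the univariable estimand for BMI is
`theta_bmi + delta * theta_whr` and for WHR equals its direct effect (no
back-path), which is what makes the attenuation contrast interpretable.

## Default preset ("biobank-like") and why

| parameter | default | rationale |
|---|---|---|
| n SNPs (BMI / WHR / shared) | 60 / 60 / 0 | polygenic, clumped-independent instruments; disjoint sets keep the univariable estimand exactly `theta + delta*theta_whr`. Shared SNPs are supported (score correlation `n_s/sqrt(m_b m_w)`, e.g. 10/40 shared ⇒ r = 0.25, the magnitude seen between real BMI and WHR scores) but off by default because overlap adds a genetic-correlation path to the univariable estimand |
| MAF range | 0.05–0.5 | common variants, as used for GWAS-derived scores |
| h² (per exposure) | 0.10 | score-captured variance giving first-stage F in the thousands at biobank n, matching the regime where weak-instrument bias is negligible |
| delta (BMI→WHR) | 0.4 SD/SD | strong co-dependence of general and central adiposity |
| theta (trig) | BMI 0, WHR 0.6 | triglycerides driven by central adiposity only; WHR direct effect ≈ 0.6 SD is the magnitude reported for VLDL triglycerides in large adult cohorts |
| theta (LDL-C) | BMI 0, WHR 0.15 | modest positive central-adiposity effect on LDL-C, of the size seen in near-untreated (young) strata |
| theta (GlycA) | BMI 0.15, WHR 0.25 | inflammatory marker with effects from both exposures |
| kappa (U loadings) | 0.3 everywhere | moderate shared confounding: enough to visibly bias conventional regression while leaving MR consistent |
| statin logit | a = −2.3, b_bmi = 0.3, b_whr = 0.5, b_ldl = 1.2, g = 0.10/yr | prescription driven mostly by the indication (latent LDL-C) plus adiposity; constants calibrated once so age-tertile prevalence runs ≈ 6% / 15% / 31% (overall ≈ 17%), the steep age gradient typical of middle-aged cohorts. A logit-linear age term cannot make the prevalence exactly linear in probability, so the youngest tertile sits slightly above the ~5% seen in practice |
| tau (treatment effect) | 1.5 SD | statins lower LDL-C by roughly 1.4 mmol/L against a ≈0.9 mmol/L population SD |
| age | Uniform(38, 73), independent of genotype and adiposity | age must be exogenous for the age-stratification argument to hold |

Sex is Bernoulli(0.5) (0 = male, 1 = female). Sex-divergent regimes are
modelled only at the exposure→outcome stage (`sex_effect_overrides`), never
as sex-specific allele effects: heterogeneity of SNP effects is not what the
stratified analyses probe, and keeping genetics common to both sexes makes
the per-sex estimands explicit.

`kappa_bmi`/`kappa_whr` are separate fields from the outcome loading
`kappa_confounder` because the exposure equations need their own confounder
loadings for the conventional-vs-MR contrast to be meaningful; a single
shared loading would tie the confounding of exposures and outcomes together
for no modelling gain.

## Estimators and numerical choices

**2SLS.** Coefficients from the projected design `(X̂'X̂)⁻¹X̂'y`;
residuals from the *observed* exposures; HC1 sandwich
`(X̂'X̂)⁻¹(Σ uᵢ² x̂ᵢx̂ᵢ')(X̂'X̂)⁻¹ · n/(n−k)`. Wald (normal) p-values;
95% CI = β ± 1.96·se. Designs with condition number above 1e10 raise a
singular-design error. Rows with any missing model variable are dropped per
model and the analysed n is reported per row. HC1 was chosen over HC0/HC3
as the standard small-sample-scaled flavour; the robust flavour is recorded
in result metadata.

**Logistic second stage.** Predictor substitution: predicted exposures from
the linear first stages enter a maximum-likelihood logistic regression.
Reported SEs are naive ML SEs (they ignore first-stage noise); an optional
nonparametric bootstrap over both stages is provided. Estimates are
population-averaged log-odds ratios, which are attenuated relative to the
conditional logit coefficients of the generator — the test suite therefore
scores this estimator against its own large-n limit, not against the
generative slopes.

**Interaction tests.** Second stage augmented with the observed modifier
and predicted-exposure × modifier, HC1 errors on the product term. The
modifier must vary within the analysis sample.

**Conditional F (Sanderson–Windmeijer).** Residualise exposures and scores
on covariates; IV-estimate X₁ on X₂ using both scores; regress the residual
X₁ − δ̂X₂ on both scores; scale the joint F by k_Z/(k_Z − k_other) = 2.
Exactly collinear exposures short-circuit to F = 0. The df scaling is
recorded in result metadata.

**IVW.** β = Σwⱼrⱼ/Σwⱼ with rⱼ = β_Y/β_X and first-order weights
wⱼ = β_X²/se_Y² (identical to zero-intercept WLS); multiplicative
random-effects SE floored at the fixed-effect SE (scale
max(1, √(Q/(J−1)))).

**MR-Egger.** Weighted regression with intercept after orienting all
β_X ≥ 0; weights 1/se_Y²; dispersion estimated from the weighted residuals
with J−2 df and t(J−2) reference, *without* the fixed-effect floor: the
floor makes the intercept (pleiotropy) test conservative and measurably
non-uniform under the null, whereas plain WLS inference is exactly
calibrated — that calibration is a property the package tests, so the
unfloored form is used for Egger only. A 1e-12 scale floor keeps SEs
positive on exactly-collinear fixtures.

**Weighted median.** First-order delta-method ratio weights
(se_Y²/β_X²)⁻¹, midpoint cumulative sums, linear interpolation at
cumulative weight 0.5. Note the midpoint convention means a SNP holding just
over half the weight pins the estimate only up to a vanishing interpolation
term. SE by parametric bootstrap (default 1000 draws, seeded).

**Weighted mode.** Weighted normal-kernel density over the ratios,
bandwidth = factor × 0.9 × weighted-SD × J^(−1/5) (weighted Silverman
analogue, factor default 1, no NOME penalty on the weights); argmax on a
512-point grid spanning [min r − 3h, max r + 3h]; ties broken toward the
smallest absolute estimate; degenerate zero spread returns the common
value. Grid resolution bounds the attainable precision and is accounted for
in tests.

**Harmonisation.** Match on SNP ID; swapped allele pairs flip the outcome
beta; strand complements are recognised; palindromic (A/T, C/G) SNPs are
kept only when effect-allele frequencies on both sides lie outside
[0.42, 0.58] and jointly identify orientation, else dropped; unresolvable
pairs dropped with a logged count.

**Ratio variances** use the first-order delta method only (no second-order
term); recorded in metadata.

## Stratification machinery

Standardise-then-stratify is fixed: exposures and outcomes are z-scored
among sexes combined, so stratum-level outcome SDs are generally ≠ 1 and
estimates stay comparable across strata. Age tertiles use empirical 1/3 and
2/3 quantiles with boundary ages assigned to the lower tertile
(deterministic ties). Sex-specific runs drop sex from the covariates.
Education/smoking/alcohol stand-ins (correlated with the confounder) enter
only the conventional comparator models, never the MR models. Grid cells
that fail raise nothing: they are logged and skipped, and grid
completeness (rows + skips = cardinality) is tested.

## What the generator does and does not emulate

It reproduces the statistical skeleton the estimators assume: polygenic
Hardy–Weinberg instruments without LD, exposure co-dependence with shared
confounding, outcome effects of both exposures, indication-driven
age-graded medication with a subtractive treatment effect, and exogenous
age. It does **not** emulate linkage disequilibrium, population structure
or PC confounding, assortative mating, imputation dosage error,
sex-specific allele effects, correlated multi-outcome noise (outcomes share
only U), proportional (rather than subtractive) treatment effects, or
selection into the cohort. Passing tests therefore certify the estimators
and the inferential machinery under the assumed model — not robustness to
the realistic violations above.

## Problem sizes in the tests and acceptance script

Single-cohort checks use n = 20k–100k; replicate studies use 150–200
replicates at n = 1.5k–20k (null calibration at the small end, recovery and
coverage at n = 20k; the acceptance script uses 60–100 replicates for its
replicated quantities). These sizes put Monte-Carlo error well below the
effect magnitudes being asserted while keeping the default suite fast on a
single CPU.

## Known limitations

* Logistic-stage SEs ignore generated-regressor noise unless the bootstrap
  is requested.
* MR-Egger is sensitive to noise in the exposure associations (NOME/I²GX
  dilution); with many individually weak SNPs it can overshoot even without
  pleiotropy, as `examples/04_twosample_mr.py` demonstrates deliberately.
* The weighted-mode argmax is grid-quantised (512 points).
* Two-sample machinery is univariable only; no outlier-removal or
  Steiger-style filtering is provided.
* No LIML/Fuller or weak-instrument-robust (Anderson–Rubin) inference: the
  intended regime has conditional F in the thousands.
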