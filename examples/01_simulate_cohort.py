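"""Generate a synthetic adiposity cohort and inspect its causal structure.

Builds a seeded biobank-like cohort (polygenic instruments, correlated BMI
and WHR exposures, metabolite outcomes, age-graded statin use) and prints
the generative truth alongside a few realised sample moments.
"""

import numpy as np

from adipomr import pipeline, simulate

cfg = simulate.ukb_like_config(seed=7, n_individuals=20_000)
cohort = simulate.simulate_cohort(cfg)
ph = cohort.phenotypes

print(f"cohort: n={len(ph)}, SNPs={cohort.genotypes.n_snps}")
print(f"direct effects on triglycerides: BMI={cfg.theta_bmi['trig']}, "
      f"WHR={cfg.theta_whr['trig']}; BMI->WHR path={cfg.delta_bmi_to_whr}")
print(f"implied total BMI effect (delta * theta_WHR): "
      f"{cfg.total_effect_bmi('trig'):.2f}")
print(f"sample corr(BMI, WHR) = {np.corrcoef(ph.bmi, ph.whr)[0, 1]:.3f} "
      f"(population value {cfg.cov_bmi_whr:.2f})")

tert, _ = pipeline.age_tertiles(ph["age"])
prev = ph.groupby(tert)["statin"].mean()
print("statin prevalence by age tertile:",
      " / ".join(f"{p:.1%}" for p in prev))
# The rising prevalence is what makes age a proxy for medication exposure:
# the youngest tertile is nearly statin-free, the oldest is ~30% treated.
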