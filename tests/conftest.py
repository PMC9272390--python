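import numpy as np
import pandas as pd
import pytest

import adipomr
from adipomr import pipeline, simulate


@pytest.fixture(scope="session")
def ukb_like_cohort():
    """One moderate biobank-like cohort reused by read-only tests."""
    cfg = simulate.ukb_like_config(seed=101, n_individuals=8000)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_phenotypes(ukb_like_cohort):
    """Phenotypes with standardised risk-score instruments attached."""
    ph = pipeline.attach_scores(ukb_like_cohort)
    return pipeline.standardise_for_analysis(ph, ["bmi", "whr", "trig", "ldl", "glyca"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_sumstats(bx, by, sx=None, sy=None, eaf=None):
    """Assemble a summary-statistics frame from raw arrays."""
    bx = np.asarray(bx, dtype=float)
    j = len(bx)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(j)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exposure": bx,
            "se_exposure": np.full(j, 0.01) if sx is None else np.asarray(sx, float),
            "beta_outcome": np.asarray(by, dtype=float),
            "se_outcome": np.full(j, 0.01) if sy is None else np.asarray(sy, float),
        }
    )
    if eaf is not None:
        df["eaf"] = eaf
    return df
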