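import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ogttrank.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (N=1350) shared across tests."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    from ogttrank.pipeline import prepare_analysis_frame

    cohort, _ = default_cohort
    frame, excluded = prepare_analysis_frame(cohort)
    return frame, excluded


def make_regression_frame(n, beta_per_allele, rng, maf=0.3, index="igi1"):
    """Direct synthetic regression data with a known per-allele effect on
    loge(index) and confounders uncorrelated with the genotype."""
    g = rng.binomial(2, maf, n)
    age = rng.uniform(25, 65, n)
    bmi = rng.uniform(20, 40, n)
    isi = np.exp(rng.normal(3.0, 0.4, n))
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    log_y = (
        2.0
        + beta_per_allele * g
        + 0.3 * (sex == "male")
        - 0.2 * np.log(bmi / 27)
        + rng.normal(0, 0.5, n)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "matsuda_isi": isi,
            index: np.exp(log_y),
            "snp": g,
        }
    )
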