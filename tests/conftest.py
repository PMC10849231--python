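import numpy as np
import pandas as pd
import pytest

from splitaudit import Cohort, GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def study_params() -> GeneratorParams:
    """Default study conditions: 700 cases, 16.3% prevalence, AUC 0.70."""
    return GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def study_cohort(study_params) -> Cohort:
    return generate_cohort(study_params)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A quick 120-case cohort with few features for pipeline plumbing tests."""
    params = GeneratorParams(
        n_cases=120,
        prevalence=0.25,
        n_radiomic=8,
        n_clinical=2,
        n_informative_radiomic=4,
        n_informative_clinical=1,
        target_population_auc=0.75,
        seed=7,
    )
    return generate_cohort(params)


def toy_cohort_frame(n=12, seed=0) -> pd.DataFrame:
    """Hand-sized table for exact-arithmetic tests."""
    rng = np.random.default_rng(seed)
    half = n // 2
    return pd.DataFrame(
        {
            "case_id": [f"case_{i:02d}" for i in range(n)],
            "vendor": ["GE"] * half + ["Hologic"] * (n - half),
            "label": [0, 1] * (n // 2),
            "age": rng.normal(60, 5, n),
            "lesion_size": rng.normal(12, 3, n),
            "f_001": rng.normal(size=n),
            "f_002": rng.normal(size=n),
            "c_001": rng.normal(size=n),
        }
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    return Cohort(toy_cohort_frame(), ["f_001", "f_002"], ["c_001"])
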