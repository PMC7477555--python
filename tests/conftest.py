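import numpy as np
import pandas as pd
import pytest

from tdluprs import GeneratorConfig, generate_cohort, make_synthetic_weights


@pytest.fixture(scope="session")
def default_cohort():
    """One default-world cohort (n = 1398), shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=2025))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort generated with no score effect on counts."""
    return generate_cohort(GeneratorConfig(prs_effect_log_rr=0.0, seed=77))


@pytest.fixture(scope="session")
def weights_table():
    return make_synthetic_weights(n_variants=313, seed=5)


@pytest.fixture()
def tiny_cohort():
    """Hand-sized cohort for closed-form checks."""
    rng = np.random.default_rng(3)
    n = 12
    return pd.DataFrame(
        {
            "subject_id": [f"T{i}" for i in range(n)],
            "study": ["KTB"] * 6 + ["STAMP"] * 6,
            "age_years": rng.uniform(25, 60, n),
            "tissue_area_mm2": rng.uniform(10, 60, n),
            "tdlu_count": rng.poisson(4, n),
            "acini_per_tdlu": rng.uniform(5, 20, n),
            "acini_per_tdlu_incl_zero": rng.uniform(5, 20, n),
            "prs_std": rng.standard_normal(n),
        }
    )


def small_config(n=400, **kw):
    """Config scaled to n samples, keeping the study proportions."""
    n_stamp = int(round(n * 309 / 1398))
    return GeneratorConfig(n_samples=n, study_split=(n - n_stamp, n_stamp), **kw)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(n=400, seed=9))
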