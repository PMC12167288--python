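import pytest

from npcat.datasets import reconstruct_study_cohort
from npcat.simulate import default_study_config, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic 137-lesion cohort matching the published aggregates."""
    return reconstruct_study_cohort()


@pytest.fixture(scope="session")
def synthetic_10k():
    """Default-configuration synthetic cohort, n = 10,000, fixed seed."""
    return generate_cohort(default_study_config(n=10_000, seed=20_240_101))


@pytest.fixture(scope="session")
def synthetic_100k():
    """Large synthetic cohort for empirical-frequency checks."""
    return generate_cohort(default_study_config(n=100_000, seed=314_159))
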