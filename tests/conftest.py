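import pytest

from benzrisk.multistage import (
    MultistageResults,
    PUBLISHED_LMS,
    chinese_benzene_cohort,
)
from benzrisk.simulate import SyntheticConfig, generate_workers, workers_to_sample_frame


@pytest.fixture(scope="session")
def cohort_groups():
    """Bundled grouped cohort (three strata of the Chinese benzene cohort)."""
    return chinese_benzene_cohort()


@pytest.fixture(scope="session")
def published_lms() -> MultistageResults:
    return PUBLISHED_LMS


@pytest.fixture(scope="session")
def synthetic_workers():
    """One default synthetic worker panel, shared across tests (seed 42)."""
    return generate_workers(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def synthetic_samples(synthetic_workers):
    return workers_to_sample_frame(synthetic_workers)
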