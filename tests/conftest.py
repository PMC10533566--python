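import numpy as np
import pytest

from salisense import DEFAULT_PANEL, generate_cohort, generate_responses
from salisense.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def responses(cohort, default_config):
    return generate_responses(cohort, DEFAULT_PANEL, default_config)


@pytest.fixture(scope="session")
def labels(cohort):
    return cohort["group"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
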