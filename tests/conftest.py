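import pytest

from emfdose.registry import load_default_registry
from emfdose.synthetic import default_marginals, fixture_table3_cohort


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def marginals():
    return default_marginals()


@pytest.fixture(scope="session")
def table3_cohort():
    return fixture_table3_cohort()
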