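import pytest

from olacea import load_config


@pytest.fixture(scope="session")
def base_case():
    """Packaged base-case configuration: (ModelConfig, EconomicInputs, arms, WTP)."""
    return load_config()


@pytest.fixture(scope="session")
def config(base_case):
    return base_case[0]


@pytest.fixture(scope="session")
def inputs(base_case):
    return base_case[1]


@pytest.fixture(scope="session")
def arms(base_case):
    return base_case[2]


@pytest.fixture(scope="session")
def wtp(base_case):
    return base_case[3]
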