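import pytest

from oxypbpk import default_config

PARENT = "cholesterol"
METABOLITE = "4b-hydroxycholesterol"


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def phys(config):
    return config.physiology


@pytest.fixture(scope="session")
def parent(config):
    return config.compounds[PARENT]


@pytest.fixture(scope="session")
def metabolite(config):
    return config.compounds[METABOLITE]
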