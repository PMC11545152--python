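import pytest

from coopclim.config import DEFAULT_HOUSE, load_preset


@pytest.fixture(scope="session")
def house():
    return DEFAULT_HOUSE


@pytest.fixture(scope="session")
def summer():
    return load_preset("summer")


@pytest.fixture(scope="session")
def autumn():
    return load_preset("autumn")


@pytest.fixture(scope="session")
def winter():
    return load_preset("winter")
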