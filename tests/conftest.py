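import pytest

from graftdyn import nominal_parameters


@pytest.fixture(scope="session")
def nominal():
    """The assembled nominal parameter set (validated against the printed table)."""
    return nominal_parameters()


@pytest.fixture(scope="session")
def params(nominal):
    return nominal.params


@pytest.fixture(scope="session")
def init(nominal):
    return nominal.init
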