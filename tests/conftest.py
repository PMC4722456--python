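import pytest

from myokin import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def wt(registry):
    return registry["wild-type"]


@pytest.fixture(scope="session")
def r759e(registry):
    return registry["R759E"]


@pytest.fixture(scope="session")
def double_mutant(registry):
    return registry["R759E/N509K"]
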