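import pytest

from enteropep import bundled_registry


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture(scope="session")
def proglucagon(registry):
    return registry["P01275"]
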