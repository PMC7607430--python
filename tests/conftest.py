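import pytest
from hypothesis import settings

from licorr.fixtures import published_fixtures
from licorr.registry import abstract_registry, default_registry

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reg():
    return default_registry()


@pytest.fixture(scope="session")
def areg():
    return abstract_registry()


@pytest.fixture(scope="session")
def examples():
    return published_fixtures()
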