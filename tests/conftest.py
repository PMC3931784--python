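import numpy as np
import pytest

from axonome.config import build_field, build_type_spec, default_config
from axonome.environment import GrowthField


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def field(config):
    return build_field(config)


@pytest.fixture(scope="session")
def big_field():
    """A long barrier-free field for asymptotic growth checks."""
    return GrowthField(rc_extent=(0.0, 20000.0))


@pytest.fixture(scope="session")
def ain_spec(config):
    return build_type_spec(config, "aIN-like")


@pytest.fixture(scope="session")
def cin_spec(config):
    return build_type_spec(config, "cIN-like")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
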