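import numpy as np
import pytest

from somnus.config import SimConfig
from somnus.fixtures import FixtureSpec, fixture_config, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return SimConfig()


@pytest.fixture
def mini_config():
    """Miniature network/environment configuration (fast epochs)."""
    return fixture_config(FixtureSpec(seed=7))


@pytest.fixture
def mini_session():
    """A deterministic miniature session: 12x12 world, 5x5 visual field."""
    return make_fixture(FixtureSpec(seed=7))
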