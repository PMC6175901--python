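import numpy as np
import pytest
from hypothesis import settings

from abvalidate import PillarConfig

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def config() -> PillarConfig:
    return PillarConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
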