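import numpy as np
import pytest
from hypothesis import settings

from lenvicb.panel import TargetPanel

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> TargetPanel:
    return TargetPanel.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
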