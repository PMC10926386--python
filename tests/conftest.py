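import numpy as np
import pytest

from egisim.genetics import GeneticsConfig
from egisim.lifecycle import LifecycleParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return GeneticsConfig()


@pytest.fixture
def fast_params():
    """Small population for quick season runs in unit tests."""
    return LifecycleParams(initial_adults=400)
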