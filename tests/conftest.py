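import numpy as np
import pytest
from hypothesis import settings

from dazzle.pipeline import make_fixtures

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic edge-case clips, tracks and the matched viewer."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240925)
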