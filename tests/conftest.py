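import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20230519)


@pytest.fixture
def rng_factory():
    def make(*key):
        return np.random.default_rng(list(key) if key else 0)

    return make
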