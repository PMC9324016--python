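import numpy as np
import pytest

from eien.synthetic import PhantomConfig, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pair():
    """One 32x32 phantom (abnormal, normal) pair."""
    return generate_pair(PhantomConfig(height=32, width=32, seed=7))


@pytest.fixture(scope="session")
def tiny_pairs():
    """Eight 32x32 phantom pairs for smoke training."""
    return [generate_pair(PhantomConfig(height=32, width=32, seed=200 + k))
            for k in range(8)]
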