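import numpy as np
import pytest

from msrn.phantom import PhantomConfig, generate_samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_batch():
    """Fifty small phantoms with labels and boxes, shared across tests."""
    cfg = PhantomConfig(side=128, seed=7)
    return generate_samples(50, cfg)
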