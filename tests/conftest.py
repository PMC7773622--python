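import numpy as np
import pytest

from trabpipe.synth import VOIRecipe, gen_voi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sample_voi():
    """One deterministic synthetic trabecular VOI."""
    return gen_voi(VOIRecipe(seed=7))


@pytest.fixture(scope="session")
def random_volumes():
    """Ten random uint8 volumes at the standard VOI shape."""
    rng = np.random.default_rng(99)
    return [rng.integers(0, 256, (20, 20, 8)).astype(np.uint8) for _ in range(10)]
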