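import numpy as np
import pytest
from hypothesis import settings

from paraseg.phantom import PhantomConfig, generate_phantoms

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_phantoms():
    """Ten default-difficulty phantoms at 128 px, shared across tests."""
    return generate_phantoms(PhantomConfig(n_images=10, image_side=128, seed=1))


@pytest.fixture(scope="session")
def easy_phantoms():
    """Crisp, well-separated phantoms (the generator's easy limit)."""
    return generate_phantoms(
        PhantomConfig(n_images=5, image_side=128, seed=2,
                      intensity_overlap=0.0, boundary_fuzz_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
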