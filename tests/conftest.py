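import numpy as np
import pytest
from hypothesis import settings

from hnseg.phantom import PhantomSpec, generate_phantom_pool

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast phantom geometry used across tests."""
    return PhantomSpec(image_size=32, n_slices=3,
                       organ_axes_inplane=(5.0, 9.0),
                       organ_axes_slices=(1.5, 2.5))


@pytest.fixture(scope="session")
def tiny_pool(tiny_spec):
    return generate_phantom_pool(tiny_spec, 4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
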