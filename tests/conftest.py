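import numpy as np
import pytest

from consegnet import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    return PhantomSpec(size=64, lesion_radius_range=(6.0, 16.0),
                       background_texture_scale=8.0, seed=7)


@pytest.fixture(scope="session")
def tiny_pair(tiny_phantom_spec):
    return generate_phantom(tiny_phantom_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
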