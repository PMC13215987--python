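import numpy as np
import pytest

from slicefat.phantom import PhantomSpec, generate_slice_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default asymmetric phantom, no noise: (image, masks, arms, abdominal)."""
    return generate_slice_phantom(PhantomSpec(noise_sd=0.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
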