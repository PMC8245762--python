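import numpy as np
import pytest

from acpcnet.synthetic_phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise/jitter-free phantom: landmarks exactly at the template positions."""
    params = PhantomParams(
        shape=(64, 64, 48), jitter_mm=0.0, noise_sigma=0.0, bias_field=False, seed=42
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
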