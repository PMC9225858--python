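import numpy as np
import pytest
from hypothesis import settings

from galiverseg.phantom import PhantomConfig, generate_slice

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return PhantomConfig(seed=7)


@pytest.fixture
def noiseless_config():
    """Two-level phantom: image equals mask exactly (liver 1, background 0)."""
    return PhantomConfig(
        liver_intensity_mean=1.0,
        liver_intensity_sd=0.0,
        confounder_count=0,
        lesion_probability=0.0,
        noise_sd=0.0,
        background_intensity_mean=0.0,
        seed=7,
    )


@pytest.fixture
def phantom_slice(default_config):
    return generate_slice(default_config, 42)


@pytest.fixture
def noiseless_slice(noiseless_config):
    return generate_slice(noiseless_config, 42)
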