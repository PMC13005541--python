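import numpy as np
import pytest

from discsignal import PhantomConfig, generate_phantom, process_subject


@pytest.fixture(scope="session")
def noise_free_config():
    """Default-grid phantom with all randomness switched off."""
    return PhantomConfig(noise_sigma=0.0, sigma_b=0.0, sigma_e=0.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_config):
    return generate_phantom(noise_free_config, 0, "control", "s0")


@pytest.fixture(scope="session")
def noise_free_extraction(noise_free_config, noise_free_phantom):
    vol, lab, _ = noise_free_phantom
    return process_subject(vol, lab, "s0")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
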