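import numpy as np
import pytest
from hypothesis import settings

from nodeseg.phantom import PhantomConfig, generate_phantom

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config():
    """Compact phantom configuration used across tests."""
    return PhantomConfig(volume_shape=(16, 48, 48), n_nodes_range=(1, 2),
                         n_vessels_range=(1, 2))


@pytest.fixture(scope="session")
def small_volume(small_config):
    sample, meta = generate_phantom(small_config, seed=7)
    return sample, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
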