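import numpy as np
import pytest

from spikesort import SimConfig
from spikesort.data import ElectrodeGeometry
from spikesort.noise_model import NoiseModel
from spikesort.synthetic import make_templates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return ElectrodeGeometry(rows=5, cols=6, pitch_um=100.0)


@pytest.fixture
def noise_model():
    # tau = 0.3 ms at 10 kHz -> AR(1) coefficient exp(-1/3) ~ 0.72
    return NoiseModel(sigma=10.0, tau=0.3e-3, dt=1e-4)


@pytest.fixture
def sim_config():
    return SimConfig(n_units=5, duration_s=10.0, seed=7)


@pytest.fixture
def small_bank(sim_config):
    return make_templates(sim_config, np.random.default_rng(sim_config.seed))
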