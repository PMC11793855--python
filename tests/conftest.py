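import numpy as np
import pytest

from neoperf.config import default_config, sim_config_from, index_windows_from
from neoperf.optics import default_geometry
from neoperf.synthetic import load_group_presets


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def sim_config(cfg):
    return sim_config_from(cfg)


@pytest.fixture(scope="session")
def windows(cfg):
    return index_windows_from(cfg)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def presets(sim_config, windows):
    return load_group_presets(sim_config, windows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
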