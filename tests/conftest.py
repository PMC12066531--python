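import numpy as np
import pytest

from planterkit.simulate import SceneConfig, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """A scene with no detector noise: detections equal truth boxes."""
    return SceneConfig(miss_prob=0.0, jitter_sd=0.0, id_gap_prob=0.0, seed=7)


@pytest.fixture
def noiseless_scene(noiseless_config):
    return simulate_scene(noiseless_config)
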