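import numpy as np
import pytest

from qppdyn.synthetic import SimulationConfig


@pytest.fixture
def default_config() -> SimulationConfig:
    """The standard study conditions: 30 regions, 480 frames at TR 1.25 s."""
    return SimulationConfig(seed=11)


@pytest.fixture
def noise_free_qpp_config() -> SimulationConfig:
    """A scan containing only the planted quasi-periodic pattern: no global
    fluctuation, no noise, regular 24-frame event spacing (20 events)."""
    return SimulationConfig(
        seed=3,
        gs_amplitude=0.0,
        noise_sd=0.0,
        voxel_noise_sd=0.0,
        interval_jitter_frames=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
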