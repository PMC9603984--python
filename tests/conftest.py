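import numpy as np
import pytest

from orgaswell import Condition, PlateLayout, SimulationConfig, make_screen_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """One 384-format plate with 6 compound-pair wells and 2+2 controls."""
    pairs = [(f"C{2*i+1:03d}", f"C{2*i+2:03d}") for i in range(6)]
    return make_screen_layout("P1", pairs, n_dmso=2, n_eact=2)


@pytest.fixture
def quiet_config():
    """Low-noise simulation config for fast, nearly deterministic wells."""
    return SimulationConfig(
        seed=7,
        organoids_per_well=6.0,
        detection_dropout_p=0.02,
        area_obs_noise_sd=5.0,
        bbox_jitter_sd=0.2,
    )


@pytest.fixture
def noise_free_config():
    return SimulationConfig(
        seed=7,
        organoids_per_well=6.0,
        detection_dropout_p=0.0,
        area_obs_noise_sd=0.0,
        bbox_jitter_sd=0.0,
        slope_noise_sd=0.0,
        baseline_area_sd=0.0,
    )
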