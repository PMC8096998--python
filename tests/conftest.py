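import numpy as np
import pytest

from spikewm.circuit import CircuitConfig
from spikewm.coding import RankPattern
from spikewm.dynamics import NoiseSpec


@pytest.fixture
def micro_cfg():
    """5-neuron circuit (4 E + 1 I, 3 coding neurons), deterministic."""
    return CircuitConfig(
        N_E=4, N_I=1, S_EE=2, N_input=3, seed=0, k_coincident=3,
        patterns=(
            ("red", RankPattern((1, 2, 3), label="red")),
            ("green", RankPattern((3, 2, 1), label="green")),
        ),
    )


@pytest.fixture
def micro_cfg_quiet(micro_cfg):
    """Same micro circuit with the background noise switched off."""
    import dataclasses
    return dataclasses.replace(
        micro_cfg, noise=NoiseSpec(mean_low=0.0, mean_high=0.0, variance=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
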