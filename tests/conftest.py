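import numpy as np
import pytest

from axoquant.synthetic_stacks import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A quick-to-render stack with all object classes present."""
    return SimulationConfig(
        box_size=(6.0, 16.9, 16.9),
        voxel_size=(0.3, 0.13, 0.13),
        n_axons=12,
        axon_length=20.0,
        outside_syn_density=0.15,
        postsyn_density=0.15,
        seed=123,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
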