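import numpy as np
import pytest

from neurostereo import StudyConfig, generate_phantom, section_phantom


@pytest.fixture
def small_config():
    """A light-weight single-arm configuration for fast unit tests."""
    return StudyConfig(
        groups=("control",),
        animals_per_group=1,
        neuron_count_true=2000,
        glia_per_neuron_mean=1.0,
        seed=7,
    )


@pytest.fixture
def small_stack(small_config):
    phantom = generate_phantom(small_config, "control", 0)
    return phantom, section_phantom(phantom, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
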