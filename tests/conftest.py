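import numpy as np
import pytest

from fiberdl.phantom import ActivityModel, NoiseModel, PhantomSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 three-neuron scene shared by read-only tests."""
    return generate_scene(PhantomSpec(image_size=64, n_somas=3, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noise_model():
    return NoiseModel(seed=5)


@pytest.fixture()
def activity_model():
    return ActivityModel(n_frames=60, seed=5)
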