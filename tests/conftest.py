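import numpy as np
import pytest

from virtualstain.autograd import use_dtype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def f64():
    """Run the autodiff engine in float64 for oracle-precision checks."""
    with use_dtype(np.float64):
        yield


@pytest.fixture(scope="session")
def small_scene():
    from virtualstain.synthetic import SceneConfig, generate_scene

    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def desk_dataset():
    """16 desk-scale 64×64 scenes with a 66:12:8-proportioned split."""
    from virtualstain.synthetic import desk_scene_config, generate_dataset

    return generate_dataset(16, desk_scene_config(seed=0))
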