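import numpy as np
import pytest

from psaseg import nn


@pytest.fixture
def float64():
    """Run a test in float64 (finite-difference checks need the precision)."""
    with nn.use_dtype(np.float64):
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_scenes():
    from psaseg.synth import tiny_scene_set
    return tiny_scene_set(8, seed=1)


@pytest.fixture(scope="session")
def tiny_model_and_cfg():
    from psaseg.config import build_model, tiny_experiment
    cfg = tiny_experiment(seed=1)
    return build_model(cfg), cfg
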