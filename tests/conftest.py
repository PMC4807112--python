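import numpy as np
import pytest

import eigenfundus as ef


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disc_model():
    """Eigen-template model trained on ten synthetic optic-disc patches."""
    patches, _ = ef.make_training_set(10, landmark="disc", patch_size=100, rng_seed=7)
    return ef.train(patches)


@pytest.fixture(scope="session")
def fovea_model():
    """Eigen-template model trained on ten synthetic fovea patches."""
    patches, _ = ef.make_training_set(10, landmark="fovea", patch_size=70, rng_seed=7)
    return ef.train(patches, landmark="fovea")


@pytest.fixture(scope="session")
def test_scene():
    """One held-out synthetic scene (image + ground truth)."""
    return ef.make_test_scenes(1, rng_seed=7)[0]


@pytest.fixture(scope="session")
def small_model(rng):
    """A cheap 5-patch model on 24 px patches for algebraic checks."""
    patches = [rng.uniform(0, 255, size=(24, 24)) for _ in range(5)]
    return ef.train(patches, landmark="disc")
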