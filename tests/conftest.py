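import numpy as np
import pytest

from bloomsat import SceneParams, default_library, generate_scene


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_scene():
    """Noisy 96x96 scene with 10 crowns, reused across read-only tests."""
    params = SceneParams(width=96, height=96, n_crowns=10, seed=42)
    image, truth = generate_scene(params)
    return params, image, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Deterministic noiseless scene for exact-recovery checks."""
    params = SceneParams(width=64, height=64, n_crowns=6, noise_sd=0.0, seed=7)
    image, truth = generate_scene(params)
    return params, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
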