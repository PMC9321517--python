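import numpy as np
import pytest

from sbda import SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless 120 s scene, 15 breaths/min at bin 10: the simplest input
    every stage must handle perfectly."""
    config = SceneConfig(
        duration_s=120.0,
        breathing_rate_bpm=15.0,
        subject_bin=10,
        noise_sigma=0.0,
        rng_seed=0,
    )
    matrix, truth = simulate_scene(config)
    return config, matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
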