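import numpy as np
import pytest

from orchardseg.synthetic import SceneConfig, generate_samples


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of deterministic synthetic scenes shared across tests."""
    return generate_samples(6, SceneConfig(image_size=160, n_apples=(1, 2)), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
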