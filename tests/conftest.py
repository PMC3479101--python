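import numpy as np
import pytest

from mtjquant.synthetic_data import SceneParams, generate_chevron_micrograph


@pytest.fixture(scope="session")
def organized_scene():
    """A clean, organized chevron scene shared across tests (256 px crop)."""
    params = SceneParams(image_size=(256, 256), noise_sd=20.0,
                         speckle_density=3.0, hole_fraction=0.0, seed=11)
    image, truth = generate_chevron_micrograph(params)
    return params, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
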