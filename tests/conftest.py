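import numpy as np
import pytest

from fishloc import scene_sim as sim
from fishloc.pipeline import score_images, simulate_scene

NOISELESS = sim.RenderParams(psf_sigma=0.0, noise_model=None)


@pytest.fixture(scope="session")
def noiseless_params():
    return NOISELESS


@pytest.fixture(scope="session")
def small_truth():
    """30 well-separated cells, nucleoid at half the cell area."""
    return sim.make_geometry(30, seed=1)


@pytest.fixture(scope="session")
def uniform_noise_scores():
    params = sim.RenderParams(psf_sigma=0.0, noise_model="poisson")
    _, images = simulate_scene(110, "uniform", seed=4, params=params)
    return score_images(images, register=False)


@pytest.fixture(scope="session")
def enriched_scores():
    _, images = simulate_scene(110, "nucleoid_enriched", seed=2, params=NOISELESS)
    return score_images(images, register=False)


@pytest.fixture(scope="session")
def excluded_scores():
    _, images = simulate_scene(110, "nucleoid_excluded", seed=3, params=NOISELESS)
    return score_images(images, register=False)


@pytest.fixture(scope="session")
def membrane_scores():
    params = sim.RenderParams(psf_sigma=0.5, noise_model="poisson")
    _, images = simulate_scene(110, "membrane", seed=5, params=params)
    return score_images(images, register=False)


@pytest.fixture(scope="session")
def geometry_320():
    return sim.make_geometry(320, image_shape=(1800, 1800), seed=6)
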