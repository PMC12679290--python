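import numpy as np
import pytest

from cherenkovdsc import (
    EmissionModel,
    ExperimentConfig,
    generate_dose_map,
    make_phantom_presets,
)


@pytest.fixture(scope="session")
def presets():
    return make_phantom_presets()


@pytest.fixture(scope="session")
def model():
    return EmissionModel()


@pytest.fixture(scope="session")
def config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def dose_maps(config):
    """Default-size dose maps for the three plan archetypes."""
    return {
        plan: generate_dose_map(plan, shape=config.shape, params=config.dose_params())
        for plan in ("tangent", "field_in_field", "vmat")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_plan():
    """5x5 grid with a 3x3 centre plateau at 100."""
    plan = np.zeros((5, 5))
    plan[1:4, 1:4] = 100.0
    return plan


@pytest.fixture
def toy_image(toy_plan):
    """Same plateau but one of the nine pixels dimmed to 10."""
    image = toy_plan.copy()
    image[1, 1] = 10.0
    return image
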