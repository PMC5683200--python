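import numpy as np
import pytest
from hypothesis import settings

from itrst.config import PipelineConfig
from itrst.phantoms import (
    ChestPhantomSpec,
    PhantomSpec,
    generate_artificial_volume,
    generate_chest_phantom,
)
from itrst.pipeline import prepare_volume

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

CHEST_SEEDS = (1, 2, 3)
CHEST_R_TARGET = 8.0
CHEST_W_F = 0.5


@pytest.fixture(scope="session")
def artificial_phantom():
    """The sphere/pole validation volume (deterministic, no seed)."""
    return generate_artificial_volume(PhantomSpec())


@pytest.fixture(scope="session")
def chest_phantoms():
    return [generate_chest_phantom(ChestPhantomSpec(seed=s)) for s in CHEST_SEEDS]


@pytest.fixture(scope="session")
def chest_config():
    return PipelineConfig(r_target=CHEST_R_TARGET)


@pytest.fixture(scope="session")
def chest_bundles(chest_phantoms, chest_config):
    """Full pipeline (preprocess .. features) on the three seeded chest
    phantoms; the expensive shared input for end-to-end tests."""
    bundles = []
    for ph in chest_phantoms:
        res = prepare_volume(ph.volume, chest_config)
        nodes = ph.ground_truth_nodes(res.preprocessed)
        bundles.append(
            {
                "candidates": res.candidates,
                "features": res.features,
                "nodes": nodes,
                "cancer_mask": None,
                "result": res,
            }
        )
    return bundles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
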