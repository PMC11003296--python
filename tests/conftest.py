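import numpy as np
import pytest

from phoskit.axon import build_axon_map
from phoskit.io import DrawingMask
from phoskit.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def axon_map():
    """Mid-resolution axon map shared across the suite."""
    return build_axon_map(n_bundles=300)


@pytest.fixture(scope="session")
def small_cohort(axon_map):
    """A compact synthetic cohort reused by pipeline-level tests."""
    cfg = CohortConfig(n_electrodes=5, n_pairs=6, trials_per_condition=3)
    return generate_cohort(cfg, seed=11, axon_map=axon_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(32, 32), density=0.4) -> np.ndarray:
    mask = rng.random(shape) < density
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def as_drawing(pixels, pitch=0.5, dist=80.0) -> DrawingMask:
    return DrawingMask(np.asarray(pixels, dtype=bool), pitch, dist)
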