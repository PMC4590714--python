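"""Shared fixtures.

The heavy end-to-end fixtures (trained SVMs, calibrated thresholds,
held-out test scenes) are session-scoped: training runs once and is
reused by the pipeline tests and the end-to-end acceptance test.  All
randomness is seeded, so the whole suite is deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

from seghog import compute_gradient_field, generate_scene_suite, train_all
from seghog.pipeline import calibrate_thresholds

logging.getLogger("seghog").setLevel(logging.ERROR)

settings.register_profile("seghog", derandomize=True, database=None, deadline=None)
settings.load_profile("seghog")

TRAIN_SEED, VAL_SEED, TEST_SEED = 100, 150, 200
N_TRAIN, N_VAL, N_TEST = 16, 8, 20


@pytest.fixture(scope="session")
def train_scenes():
    return generate_scene_suite(N_TRAIN, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def test_scenes():
    return generate_scene_suite(N_TEST, seed=TEST_SEED)


@pytest.fixture(scope="session")
def trained(train_scenes):
    """(models, calibrated config): three SVMs trained on the training
    suite, thresholds calibrated on a disjoint validation suite."""
    import warnings

    val_scenes = generate_scene_suite(N_VAL, seed=VAL_SEED)
    imgs = [s[0] for s in train_scenes]
    truths = [s[1] for s in train_scenes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = train_all(imgs, truths, seed=0)
        config = calibrate_thresholds(
            models, [s[0] for s in val_scenes], [s[1] for s in val_scenes]
        )
    return models, config


@pytest.fixture(scope="session")
def paraboloid_field():
    """Gradient field whose gx/gy are exactly linear, so bilinear
    resampling is exact and radial symmetry holds to machine precision."""
    rows, cols = np.indices((240, 240))
    img = ((rows - 120.0) ** 2 + (cols - 120.0) ** 2) / 100.0
    return compute_gradient_field(img), (120.0, 120.0)
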