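"""Shared fixtures: small desk-scale scenes and datasets."""

import numpy as np
import pytest

from uwbfall.preprocess import PreprocessConfig
from uwbfall.radar_sim import (
    PulseParams,
    default_subjects,
    generate_dataset,
    make_scene,
)

TINY_BINS = 32


@pytest.fixture(scope="session")
def tiny_pulse():
    """32-bin frames spanning the full room extent (coarse fast time)."""
    return PulseParams().with_bins(TINY_BINS)


@pytest.fixture(scope="session")
def tiny_scene(tiny_pulse):
    return make_scene("lab", pulse=tiny_pulse, seed=11, noise_sigma=0.02)


@pytest.fixture(scope="session")
def tiny_config():
    return PreprocessConfig(n_bins=TINY_BINS)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scene):
    """2 subjects x 6 activities x 4 recordings at 32 bins."""
    subjects = default_subjects(2, seed=11)
    return generate_dataset(tiny_scene, subjects, 4, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
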