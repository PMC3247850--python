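"""Shared fixtures: small synthetic subjects sized for fast unit tests."""

import logging

import pytest

from bcifes.synth import SynthConfig, generate_recording
from bcifes.workflow import preprocess_recording, train_from_recording

logging.getLogger("bcifes").setLevel(logging.ERROR)


def small_config(**overrides) -> SynthConfig:
    """A light subject: 16 channels, 12 trials/class, low-rate goniometer."""
    defaults = dict(
        n_channels=16,
        n_epochs_per_class=12,
        fs_gonio=500.0,
        seed=7,
        subject_seed=7,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    return preprocess_recording(small_recording)


@pytest.fixture(scope="session")
def small_model(small_recording):
    """A trained model on the small subject (reduced CV for speed)."""
    return train_from_recording(small_recording, folds=4, runs=1, seed=7)
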