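"""Shared fixtures: small calibrated models trained once per session."""

from __future__ import annotations

import pytest

from whalescan import (
    SceneSpec,
    TrainingConfig,
    generate_classification_dataset,
    generate_detection_dataset,
    train_detector,
    train_presence_classifier,
)

# Reference study conditions for the small calibrated fixture models: 1 m
# pixels so a 71 px patch is one 71 m grid cell.
SPEC_TEMPLATE = SceneSpec(pixel_size=1.0)


@pytest.fixture(scope="session")
def classification_dataset():
    return generate_classification_dataset(
        n_per_class=60, patch_size=71, spec_template=SPEC_TEMPLATE, seed=0
    )


@pytest.fixture(scope="session")
def presence_classifier(classification_dataset):
    return train_presence_classifier(
        classification_dataset, TrainingConfig(epochs=20, seed=0)
    )


@pytest.fixture(scope="session")
def detection_dataset():
    return generate_detection_dataset(
        n_images=100, patch_size=128, spec_template=SPEC_TEMPLATE, seed=0
    )


@pytest.fixture(scope="session")
def whale_detector(detection_dataset):
    return train_detector(detection_dataset, TrainingConfig(epochs=20, seed=0))
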