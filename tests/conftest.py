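"""Shared fixtures: small synthetic screens and a briefly trained encoder."""

from __future__ import annotations

import numpy as np
import pytest

from phenocon.contrastive import ContrastiveConfig, train_semisupervised
from phenocon.io_data import preprocess_records
from phenocon.synthetic import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> SynthSpec:
    return SynthSpec(
        n_classes=4,
        n_compounds=16,
        replicates_per_compound=3,
        image_hw=(32, 32),
        n_channels=5,
        annotation_fraction=0.5,
        multilabel_fraction=0.25,
        n_controls=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    records, annotations, truth = generate_dataset(tiny_spec)
    return records, annotations, truth


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_dataset):
    records, annotations, truth = tiny_dataset
    return preprocess_records(records), annotations, truth


@pytest.fixture(scope="session")
def tiny_model(tiny_preprocessed):
    """An encoder trained for a handful of epochs on the tiny screen."""
    records, annotations, _ = tiny_preprocessed
    config = ContrastiveConfig(
        projector_dim=16, feature_dim=32, batch_size=16, max_epochs=4, seed=7
    )
    model, history = train_semisupervised(records, annotations, config)
    return model, history
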