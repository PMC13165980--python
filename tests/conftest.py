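"""Shared fixtures: small synthetic datasets and trained tiny models."""

from __future__ import annotations

import numpy as np
import pytest

import lesiontree as lt
from lesiontree.backbones import BackboneSpec, TrainingConfig


@pytest.fixture(scope="session")
def small_dataset():
    """12 images per class at 32 px — enough to exercise the pipeline."""
    return lt.generate_dataset(per_class_counts=12, image_size=32, seed=7)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    """Class-stratified 9/3 split so every class appears on both sides."""
    train, test = [], []
    seen: dict = {}
    for r in small_dataset:
        seen[r.label] = seen.get(r.label, 0) + 1
        (test if seen[r.label] <= 3 else train).append(r)
    return train, test


@pytest.fixture(scope="session")
def tiny_spec32():
    return BackboneSpec(name="tiny_test_cnn", input_size=32)


@pytest.fixture(scope="session")
def quick_config():
    return TrainingConfig(max_epochs=5, mini_batch_size=16, seed=0)


@pytest.fixture(scope="session")
def trained_root_model(small_split, tiny_spec32, quick_config):
    """A tiny CNN trained on the benign-vs-malignant root task."""
    from lesiontree.hierarchy import node_training_pool

    train, _ = small_split
    node = lt.decision_nodes(lt.default_taxonomy())[0]
    pool = node_training_pool(train, node)
    model = lt.build_backbone(tiny_spec32, 2, ["positive", "negative"], seed=0)
    return lt.finetune(model, pool, None, quick_config)


def perfect_stub(node):
    """Node predictor that always takes the correct branch."""

    def predict(records):
        return np.array(
            [[1.0, 0.0] if r.label in node.positive_set else [0.0, 1.0] for r in records]
        )

    return predict
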