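"""Shared fixtures: phantom datasets and tiny trained networks.

Training fixtures are session-scoped so the (CPU-minutes) training smoke
runs happen exactly once and are reused by module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from somamapper.classifier import ClassifierConfig, build_classifier, train_classifier
from somamapper.phantom import PhantomSpec, generate_classification_set, generate_phantom
from somamapper.segmenter import SegmenterConfig, build_segmenter, train_segmenter

SEG_SMOKE_CONFIG = dict(
    K=8, window=(2, 2, 2), heads=2, crop=32, lr=3e-3,
    max_epochs=30, iters_per_epoch=6, patience=30, seed=0,
)
CLS_SMOKE_CONFIG = dict(
    stem_channels=8, stage_channels=(8, 16, 32, 64), input_size=64,
    lr=0.05, batch_size=8, max_epochs=20, patience=10, seed=0,
)


def phantom_block(seed: int, shape=(32, 32, 32), n_somata=3):
    """A small phantom (volume, mask) pair for segmentation training."""
    s = generate_phantom(PhantomSpec(
        shape=shape, n_somata=n_somata, radius_range=(3, 5),
        intensity_range=(0.6, 1.0), noise_sigma=0.05, seed=seed,
    ))
    return s.volume.data, s.mask.astype(np.float32)


@pytest.fixture(scope="session")
def mip_dataset():
    """Separable MIP set: 20 soma-bearing vs 20 background-only projections."""
    spec = PhantomSpec(shape=(64, 64, 64), n_somata=4, radius_range=(3, 6),
                       intensity_range=(0.5, 1.0), n_noise_blobs=3,
                       noise_sigma=0.05, seed=0)
    images, labels = generate_classification_set(spec, 20, 20)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(images))
    train_idx, val_idx = perm[:28], perm[28:]
    return {
        "train": (images[train_idx], labels[train_idx]),
        "val": (images[val_idx], labels[val_idx]),
    }


@pytest.fixture(scope="session")
def trained_classifier(mip_dataset):
    cfg = ClassifierConfig(**CLS_SMOKE_CONFIG)
    model = build_classifier(cfg)
    model, history = train_classifier(
        model, mip_dataset["train"], mip_dataset["val"], cfg)
    return model, history


@pytest.fixture(scope="session")
def seg_dataset():
    train = [phantom_block(i) for i in range(6)]
    val = [phantom_block(100 + i) for i in range(2)]
    test = [phantom_block(200 + i) for i in range(2)]
    return {"train": train, "val": val, "test": test}


@pytest.fixture(scope="session")
def trained_segmenter(seg_dataset):
    cfg = SegmenterConfig(**SEG_SMOKE_CONFIG)
    model = build_segmenter(cfg)
    model, history = train_segmenter(
        model, seg_dataset["train"], seg_dataset["val"], cfg)
    return model, history
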