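"""Shared fixtures: a synthetic tile corpus, a trained two-stage model and
an on-disk synthetic study, all session-scoped because they are the
expensive inputs reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from stromascore.classifier import (
    TileDataset,
    TrainConfig,
    fine_tune,
    pretrain,
    pretrain_defaults,
)
from stromascore.synthetic import generate_study, generate_tile_corpus

CORPUS_TILES_PER_CLASS = 80
CORPUS_SIDE = 224


@pytest.fixture(scope="session")
def tile_corpus():
    tiles, labels = generate_tile_corpus(
        CORPUS_TILES_PER_CLASS, side_px=CORPUS_SIDE, rng_seed=0
    )
    return tiles, labels


@pytest.fixture(scope="session")
def corpus_split(tile_corpus):
    """Disjoint train/held-out halves, stratified by the seeded shuffle."""
    tiles, labels = tile_corpus
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(tiles))
    half = len(idx) // 2
    train = TileDataset([tiles[i] for i in idx[:half]], labels[idx[:half]], "pretrain")
    test = TileDataset([tiles[i] for i in idx[half:]], labels[idx[half:]], "test")
    return train, test


@pytest.fixture(scope="session")
def trained_model(corpus_split):
    """Two-stage model: pretrain then fine-tune with the transfer recipe."""
    train, _ = corpus_split
    model = pretrain(train, pretrain_defaults(seed=1))
    finetune = TileDataset(train.tiles, train.labels, "finetune")
    return fine_tune(model, finetune, TrainConfig(epochs=10, seed=2))


@pytest.fixture(scope="session")
def model_path(trained_model, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "model.bin"
    trained_model.save(path)
    return path


@pytest.fixture(scope="session")
def study_dirs(tmp_path_factory):
    """Synthetic 30-patient development + 12-patient validation study."""
    root = tmp_path_factory.mktemp("study")
    generate_study(root / "dev", 30, rng_seed=1)
    generate_study(root / "val", 12, rng_seed=2)
    return root / "dev", root / "val"
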