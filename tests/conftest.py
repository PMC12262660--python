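"""Shared fixtures: synthetic corpora and trained models, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from zfmotor.behavior_model import evaluate, split_train_test, train
from zfmotor.config import RunConfig
from zfmotor.synthetic_fish import SimConfig, make_training_corpus

CORPUS_SEED = 11


@pytest.fixture(scope="session")
def p24_sim() -> SimConfig:
    return SimConfig(plate_format="P24", seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def p96_sim() -> SimConfig:
    return SimConfig(plate_format="P96", seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def p24_corpus(p24_sim):
    return make_training_corpus(config=p24_sim)


@pytest.fixture(scope="session")
def p96_corpus(p96_sim):
    return make_training_corpus(config=p96_sim)


def _fit(corpus, plate_format):
    clips, labels = corpus
    config = RunConfig(plate_format=plate_format)
    train_idx, test_idx = split_train_test(
        labels, config.split_fraction, config.split_seed
    )
    bundle = train(clips[train_idx], labels[train_idx], config)
    report = evaluate(bundle, clips[test_idx], labels[test_idx])
    return bundle, report, (train_idx, test_idx)


@pytest.fixture(scope="session")
def p24_model(p24_corpus):
    """(bundle, held-out EvalReport, (train_idx, test_idx)) for 24-well."""
    return _fit(p24_corpus, "P24")


@pytest.fixture(scope="session")
def p96_model(p96_corpus):
    return _fit(p96_corpus, "P96")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
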