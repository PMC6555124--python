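"""Shared fixtures: small synthetic corpora and a trained desk-scale model.

Training fixtures are session-scoped so the suite trains each model once.
Model geometry in fixtures is scaled down (shorter sequences, narrower
layers) relative to the reference configuration; geometry-sensitive tests
construct the reference configuration explicitly.
"""

import numpy as np
import pytest

from venuerec.cnn_model import ModelConfig
from venuerec.pipeline import fit_model
from venuerec.synthetic import SyntheticSpec, generate_corpus


def small_config(n_classes: int, seed: int = 1, **overrides) -> ModelConfig:
    base = dict(
        m=100,
        k=24,
        conv_stages=((16, 3), (16, 4), (16, 5)),
        hidden_sizes=(64, 32),
        n_classes=n_classes,
        batch_size=32,
        max_epochs=30,
        learning_rate=2e-3,
        seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def separable_corpus():
    """5 journals x 40 abstracts with disjoint topic vocabularies."""
    spec = SyntheticSpec(
        n_classes=5,
        class_sizes=(40,) * 5,
        vocab_size=600,
        topic_sharpness=1.0,
        seed=3,
    )
    records, class_vocab = generate_corpus(spec)
    return spec, records, class_vocab


@pytest.fixture(scope="session")
def overfit_run(separable_corpus):
    """Train on the separable corpus until (near-)perfect training accuracy.

    Returns (model, vocabulary, records); the training history is the
    record of how fast the network fit the data.
    """
    _, records, _ = separable_corpus
    config = small_config(n_classes=5, max_epochs=200)
    model, vocab = fit_model(records, config=config, stop_at_train_acc=0.995)
    return model, vocab, records
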