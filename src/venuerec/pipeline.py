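"""High-level glue: fit a model on labelled records and evaluate rankings.

These helpers wire the stages together the way the command-line interface
and the examples use them: tokenize and encode the training records, build
or accept a vocabulary and embedding table, train the network, and turn
batch probabilities into full ranked label lists for the evaluation module.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .cnn_model import (
    CNNModel,
    ModelConfig,
    predict_proba,
    prepare_dataset,
    train,
    vocab_digest,
)
from .corpus_io import PaperRecord
from .embeddings import EmbeddingTable, embedding_matrix
from .text_prep import build_vocabulary, tokenize

__all__ = ["fit_model", "rank_batch", "predict_rankings"]


def fit_model(
    train_records: Sequence[PaperRecord],
    val_records: Sequence[PaperRecord] | None = None,
    config: ModelConfig | None = None,
    *,
    vocabulary: Mapping[str, int] | None = None,
    table: EmbeddingTable | None = None,
    epochs: int | None = None,
    stop_at_train_acc: float | None = None,
) -> tuple[CNNModel, dict[str, int]]:
    """Train a classifier on labelled records; returns (model, vocabulary).

    The class set is the sorted journal labels present in the training
    records. When no embedding table is given the embedding matrix is
    initialised with small random vectors (seeded from the config) and
    fine-tuned during training; with a table, vectors are copied in and
    out-of-table tokens start at zero.
    """
    if not train_records:
        raise ValueError("empty training set")
    class_labels = sorted({r.journal_label for r in train_records})
    if vocabulary is None:
        vocabulary = build_vocabulary(tokenize(r.abstract_text) for r in train_records)
    if config is None:
        config = ModelConfig(n_classes=len(class_labels))
    elif config.n_classes != len(class_labels):
        raise ValueError(
            f"config.n_classes={config.n_classes} but {len(class_labels)} labels in data"
        )

    if table is not None:
        E = embedding_matrix(table, vocabulary)
        if table.k != config.k:
            raise ValueError(f"table dimension {table.k} != config.k {config.k}")
    else:
        rng = np.random.default_rng(config.seed + 2)
        n_vocab = max(vocabulary.values(), default=0) + 1
        E = rng.normal(0.0, 0.1, size=(n_vocab, config.k)).astype(np.float32)
        E[0] = 0.0

    model = CNNModel(config, E, class_labels, vocab_hash=vocab_digest(vocabulary))
    ids, y = prepare_dataset(train_records, vocabulary, class_labels, m=config.m)
    if val_records:
        val_ids, val_y = prepare_dataset(val_records, vocabulary, class_labels, m=config.m)
    else:
        val_ids = val_y = None
    train(
        model, ids, y, val_ids, val_y, epochs=epochs, stop_at_train_acc=stop_at_train_acc
    )
    return model, dict(vocabulary)


def rank_batch(S: np.ndarray, class_labels: Sequence[str]) -> list[list[str]]:
    """Full ranked label list per row of a (N, T) probability array.

    ``class_labels`` must be in ascending order; a stable argsort on the
    negated probabilities then breaks ties by ascending label, matching
    ``recommender.rank_probabilities``.
    """
    labels = list(class_labels)
    if labels != sorted(labels):
        raise ValueError("class_labels must be sorted ascending for stable tie-breaks")
    order = np.argsort(-np.asarray(S), axis=1, kind="stable")
    return [[labels[j] for j in row] for row in order]


def predict_rankings(
    model: CNNModel,
    vocabulary: Mapping[str, int],
    records: Sequence[PaperRecord],
    batch_size: int = 256,
) -> tuple[list[list[str]], list[str]]:
    """Ranked label lists and true labels for a set of records."""
    ids, y = prepare_dataset(records, vocabulary, model.class_labels, m=model.config.m)
    S = predict_proba(model, ids, batch_size=batch_size)
    ranked = rank_batch(S, model.class_labels)
    truth = [model.class_labels[i] for i in y]
    return ranked, truth
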