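"""Turn an abstract into a ranked top-N journal list."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cnn_model import CNNModel
from .text_prep import encode_sequence, tokenize

__all__ = ["RecommendationList", "rank_probabilities", "recommend"]


@dataclass(frozen=True)
class RecommendationList:
    """Ordered (journal_label, probability) pairs, highest probability first."""

    entries: tuple[tuple[str, float], ...]
    warnings: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.entries]

    def to_tsv(self) -> str:
        lines = ["rank\tjournal_label\tprobability"]
        lines += [f"{i+1}\t{lbl}\t{p:.6f}" for i, (lbl, p) in enumerate(self.entries)]
        return "\n".join(lines) + "\n"


def rank_probabilities(
    S: np.ndarray, class_labels: Sequence[str], N: int
) -> RecommendationList:
    """Top-N journals by class probability.

    Ties are broken by ascending journal label, so the ranking is a stable,
    documented total order and identical across runs.
    """
    S = np.asarray(S, dtype=np.float64)
    T = len(class_labels)
    if S.shape != (T,):
        raise ValueError(f"probability vector length {S.shape} != {T} labels")
    if not 1 <= N <= T:
        raise ValueError(f"N={N} out of range [1, {T}]")
    order = sorted(range(T), key=lambda i: (-S[i], class_labels[i]))
    entries = tuple((class_labels[i], float(S[i])) for i in order[:N])
    return RecommendationList(entries=entries)


def recommend(
    model: CNNModel,
    vocabulary: Mapping[str, int],
    abstract_text: str,
    N: int = 10,
    min_token_warning: int = 20,
) -> RecommendationList:
    """Rank journals for a raw abstract: tokenize, encode, forward, rank.

    Pure given a fixed model (dropout is off at inference). Abstracts with
    fewer than ``min_token_warning`` tokens are still scored, with a warning
    attached — the training corpus length filter does not apply to queries.
    """
    if not abstract_text or not abstract_text.strip():
        raise ValueError("abstract text is empty")
    tokens = tokenize(abstract_text)
    warnings: tuple[str, ...] = ()
    if len(tokens) < min_token_warning:
        warnings = (
            f"abstract has only {len(tokens)} tokens (< {min_token_warning}); "
            "recommendations may be unreliable",
        )
    seq = encode_sequence(tokens, vocabulary, m=model.config.m)
    scores = model.forward(seq.token_ids)
    ranked = rank_probabilities(scores.S, model.class_labels, N)
    return RecommendationList(entries=ranked.entries, warnings=warnings)
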