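"""Tokenization, abstract length statistics, and fixed-length encoding.

Abstracts are segmented into word and punctuation tokens, mapped to integer
ids through a corpus vocabulary, and padded or tail-truncated to a fixed
sequence length ``m`` (350 by default — long enough that only the longest
few percent of biomedical abstracts are truncated).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TokenSequence",
    "LengthHistogram",
    "DEFAULT_LENGTH_BIN_EDGES",
    "PAD_ID",
    "tokenize",
    "length_histogram",
    "build_vocabulary",
    "encode_sequence",
    "decode_sequence",
    "write_vocabulary",
    "read_vocabulary",
]

#: id 0 is reserved: padding at encode time, and any out-of-vocabulary token.
PAD_ID = 0

#: Word-count bin edges for abstract length reporting:
#: [0,20), [20,50), [50,100), ..., [300,350), and >=350.
DEFAULT_LENGTH_BIN_EDGES = (20, 50, 100, 150, 200, 250, 300, 350)

# Words keep internal hyphens and apostrophes ("p53-mediated", "crohn's");
# every other non-space symbol becomes its own token.
_TOKEN_RE = re.compile(r"\w+(?:['\-]\w+)*|[^\w\s]")


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Segment text into word and punctuation tokens.

    Deterministic regex segmentation: runs of word characters (with internal
    hyphens/apostrophes kept, so "p53-mediated" is a single token) form word
    tokens; punctuation is split off as individual tokens. Case is folded to
    lowercase by default, matching the predominantly lowercase vocabularies
    of pretrained biomedical word vectors.

    Raises ``ValueError`` on empty or whitespace-only input.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class LengthHistogram:
    """Word-count histogram over a tokenized corpus."""

    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]  # len(bin_edges)+1 bins: [0,e0), [e0,e1), ..., [e_last, inf)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def labels(self) -> list[str]:
        edges = self.bin_edges
        out = [f"x<{edges[0]}"]
        out += [f"{a}<=x<{b}" for a, b in zip(edges, edges[1:])]
        out.append(f"x>={edges[-1]}")
        return out

    def to_tsv(self) -> str:
        lines = ["bin\tcount"]
        lines += [f"{lbl}\t{c}" for lbl, c in zip(self.labels(), self.counts)]
        return "\n".join(lines) + "\n"


def length_histogram(
    corpus: Iterable[Sequence[str]],
    bin_edges: Sequence[int] = DEFAULT_LENGTH_BIN_EDGES,
) -> LengthHistogram:
    """Histogram of per-abstract token counts.

    Bins are [0, e0), [e0, e1), ..., [e_last, inf) so every abstract falls in
    exactly one bin and counts sum to the corpus size.
    """
    edges = np.asarray([0, *bin_edges, np.inf], dtype=float)
    lengths = np.array([len(toks) for toks in corpus], dtype=float)
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthHistogram(bin_edges=tuple(bin_edges), counts=tuple(int(c) for c in counts))


def build_vocabulary(
    corpus: Iterable[Sequence[str]], min_count: int = 1
) -> dict[str, int]:
    """Token -> id mapping over a corpus, ids starting at 1 (0 is reserved).

    Ids are assigned by descending frequency (ties broken alphabetically),
    so the mapping is deterministic for a given corpus.
    """
    from collections import Counter

    counts: Counter[str] = Counter()
    for toks in corpus:
        counts.update(toks)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {tok: i + 1 for i, (tok, n) in enumerate(ordered) if n >= min_count}


@dataclass(frozen=True)
class TokenSequence:
    """A fixed-length integer encoding of one abstract."""

    token_ids: np.ndarray  # int32, shape (m,)
    true_length: int  # token count before padding/truncation
    m: int

    def __post_init__(self):
        if len(self.token_ids) != self.m:
            raise ValueError(f"token_ids has length {len(self.token_ids)}, expected m={self.m}")


def encode_sequence(
    tokens: Sequence[str], vocabulary: Mapping[str, int], m: int = 350
) -> TokenSequence:
    """Encode tokens as a length-``m`` id sequence.

    Shorter inputs are zero-padded at the tail; longer inputs keep their
    first ``m`` tokens (tail truncation). Out-of-vocabulary tokens get
    ``PAD_ID`` (their word vectors resolve to zeros downstream, the same
    rule applied to padding).
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    if not tokens:
        raise ValueError("cannot encode an empty token list")
    ids = np.zeros(m, dtype=np.int32)
    for i, tok in enumerate(tokens[:m]):
        ids[i] = vocabulary.get(tok, PAD_ID)
    return TokenSequence(token_ids=ids, true_length=len(tokens), m=m)


def decode_sequence(
    seq: TokenSequence, vocabulary: Mapping[str, int], oov_token: str = "<unk>"
) -> list[str]:
    """Recover the first ``min(true_length, m)`` tokens of an encoded abstract."""
    inverse = {i: t for t, i in vocabulary.items()}
    n = min(seq.true_length, seq.m)
    return [inverse.get(int(i), oov_token) for i in seq.token_ids[:n]]


def write_vocabulary(vocabulary: Mapping[str, int], path) -> None:
    """One ``token<TAB>id`` pair per line, ordered by id."""
    with open(path, "w") as fh:
        for tok, idx in sorted(vocabulary.items(), key=lambda kv: kv[1]):
            fh.write(f"{tok}\t{idx}\n")


def read_vocabulary(path) -> dict[str, int]:
    vocab: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                tok, idx = line.rstrip("\n").split("\t")
                vocab[tok] = int(idx)
    return vocab
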