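"""Word vectors and the abstract input matrix.

Provides a word-embedding table that reads and writes the word2vec text and
binary interchange formats, a compact skip-gram trainer with hierarchical
softmax and frequent-word subsampling, and the construction of the m-by-k
abstract matrix V whose row i is the vector of token i (zero rows for
padding and out-of-vocabulary tokens).
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .text_prep import PAD_ID, TokenSequence

__all__ = [
    "EmbeddingTable",
    "AbstractMatrix",
    "load_word_vectors",
    "save_word_vectors",
    "train_skipgram",
    "embed_abstract",
    "embedding_matrix",
]


@dataclass
class EmbeddingTable:
    """vocabulary -> k-dimensional real vectors; absent tokens map to zeros."""

    k: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for tok, vec in self.vectors.items():
            if vec.shape != (self.k,):
                raise ValueError(f"vector for {tok!r} has shape {vec.shape}, expected ({self.k},)")

    @property
    def zero_vector(self) -> np.ndarray:
        return np.zeros(self.k, dtype=np.float32)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, token: str) -> np.ndarray:
        """The vector for ``token``, or the all-zero vector if absent."""
        vec = self.vectors.get(token)
        return self.zero_vector if vec is None else vec

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.lookup(a), self.lookup(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def save_word_vectors(table: EmbeddingTable, path, binary: bool = False) -> None:
    """Write a table in word2vec interchange format (text or binary).

    The binary dialect is the de-facto standard: an ASCII ``"<count> <dim>"``
    header line, then per token the token bytes, a space, and ``dim``
    little-endian float32 values.
    """
    tokens = sorted(table.vectors)
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"{len(tokens)} {table.k}\n".encode())
            for tok in tokens:
                fh.write(tok.encode("utf-8") + b" ")
                fh.write(np.asarray(table.vectors[tok], dtype="<f4").tobytes())
                fh.write(b"\n")
    else:
        with open(path, "w") as fh:
            fh.write(f"{len(tokens)} {table.k}\n")
            for tok in tokens:
                vals = " ".join(f"{v:.6g}" for v in table.vectors[tok])
                fh.write(f"{tok} {vals}\n")


def _load_text(path, expected_k):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad word2vec text header: {header!r}")
        n, k = int(header[0]), int(header[1])
        if expected_k is not None and k != expected_k:
            raise ValueError(f"embedding dimension {k} != expected {expected_k}")
        vectors = {}
        for _ in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"truncated word2vec file: expected {n} rows, got {len(vectors)}")
            parts = line.rstrip("\n").split(" ")
            tok, vals = parts[0], parts[1:]
            if len(vals) != k:
                raise ValueError(f"row for {tok!r} has {len(vals)} values, expected {k}")
            vectors[tok] = np.asarray(vals, dtype=np.float32)
    return EmbeddingTable(k=k, vectors=vectors)


def _load_binary(path, expected_k):
    with open(path, "rb") as fh:
        header = fh.readline().split()
        n, k = int(header[0]), int(header[1])
        if expected_k is not None and k != expected_k:
            raise ValueError(f"embedding dimension {k} != expected {expected_k}")
        vectors = {}
        for _ in range(n):
            tok_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise ValueError("truncated word2vec binary file (header token)")
                if ch == b" ":
                    break
                if ch != b"\n":  # leading newline from previous row
                    tok_bytes.extend(ch)
            buf = fh.read(4 * k)
            if len(buf) != 4 * k:
                raise ValueError("truncated word2vec binary file (vector data)")
            vectors[tok_bytes.decode("utf-8")] = np.frombuffer(buf, dtype="<f4").copy()
    return EmbeddingTable(k=k, vectors=vectors)


def load_word_vectors(path, expected_k: int | None = None, binary: bool | None = None) -> EmbeddingTable:
    """Read a word2vec-format embedding table (text or binary).

    ``binary=None`` sniffs the format: a file whose first line decodes as a
    two-integer ASCII header followed by text rows is treated as text when
    the second line is valid UTF-8 text, otherwise binary.
    """
    if binary is None:
        with open(path, "rb") as fh:
            fh.readline()
            probe = fh.read(512)
        try:
            probe.decode("utf-8")
            binary = False
        except UnicodeDecodeError:
            binary = True
    return _load_binary(path, expected_k) if binary else _load_text(path, expected_k)


# --- skip-gram with hierarchical softmax -----------------------------------

def _huffman_paths(counts: list[tuple[str, int]]):
    """Build Huffman codes over the vocabulary by frequency.

    Returns per-token (inner-node index path, binary code) pairs. Ties are
    broken by insertion order for determinism.
    """
    heap = [(cnt, i, None, None) for i, (tok, cnt) in enumerate(counts)]
    heapq.heapify(heap)
    next_id = len(counts)
    nodes = {}
    while len(heap) > 1:
        c1, i1, l1, r1 = heapq.heappop(heap)
        c2, i2, l2, r2 = heapq.heappop(heap)
        nodes[next_id] = (i1, i2)
        heapq.heappush(heap, (c1 + c2, next_id, i1, i2))
        next_id += 1
    root = heap[0][1]

    paths: dict[int, tuple[list[int], list[int]]] = {}

    def walk(node: int, point: list[int], code: list[int]):
        if node < len(counts):
            paths[node] = (list(point), list(code))
            return
        inner = node - len(counts)  # inner-node parameter index
        left, right = nodes[node]
        walk(left, point + [inner], code + [0])
        walk(right, point + [inner], code + [1])

    if root < len(counts):  # single-token vocabulary
        paths[root] = ([], [])
    else:
        walk(root, [], [])
    return paths


def train_skipgram(
    corpus: Iterable[Sequence[str]],
    k: int = 200,
    window: int = 5,
    subsample_threshold: float = 1e-3,
    mode: str = "hierarchical_softmax",
    epochs: int = 5,
    learning_rate: float = 0.025,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingTable:
    """Train skip-gram word vectors with hierarchical softmax.

    The classic word2vec recipe: for each center word, context words within a
    per-position random window of at most ``window`` are predicted through a
    Huffman-tree output layer; frequent words are randomly discarded with
    probability ``1 - sqrt(t/f)`` where ``f`` is the corpus frequency and
    ``t`` the subsampling threshold. Single-worker and seeded, so the result
    is reproducible. Intended for modest corpora; vectors for large corpora
    are normally loaded pretrained via :func:`load_word_vectors`.
    """
    if mode != "hierarchical_softmax":
        raise ValueError(f"unsupported training mode: {mode!r}")
    sentences = [list(s) for s in corpus]
    total_tokens = sum(len(s) for s in sentences)
    if total_tokens <= window:
        raise ValueError(f"corpus of {total_tokens} tokens is smaller than window {window}")

    freq: Counter[str] = Counter()
    for s in sentences:
        freq.update(s)
    vocab_counts = sorted(
        ((t, c) for t, c in freq.items() if c >= min_count), key=lambda kv: (-kv[1], kv[0])
    )
    if not vocab_counts:
        raise ValueError("empty vocabulary after min_count pruning")
    index = {tok: i for i, (tok, _) in enumerate(vocab_counts)}
    paths = _huffman_paths(vocab_counts)

    n_vocab = len(vocab_counts)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((n_vocab, k), dtype=np.float32) - 0.5) / k
    W_inner = np.zeros((max(1, n_vocab - 1), k), dtype=np.float32)

    keep_prob = np.ones(n_vocab)
    for tok, cnt in vocab_counts:
        f = cnt / total_tokens
        if f > subsample_threshold:
            keep_prob[index[tok]] = np.sqrt(subsample_threshold / f)

    encoded = [[index[t] for t in s if t in index] for s in sentences]
    alpha = learning_rate
    for _epoch in range(epochs):
        for sent in encoded:
            kept = [w for w in sent if rng.random() < keep_prob[w]]
            for pos, center in enumerate(kept):
                b = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - b), min(len(kept), pos + b + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    target = kept[ctx_pos]
                    point, code = paths[target]
                    if not point:
                        continue
                    v = W_in[center]
                    pts = np.asarray(point)
                    codes = np.asarray(code, dtype=np.float32)
                    z = W_inner[pts] @ v
                    p = 1.0 / (1.0 + np.exp(-np.clip(z, -16, 16)))
                    g = (alpha * (1.0 - codes - p)).astype(np.float32)
                    dv = g @ W_inner[pts]
                    W_inner[pts] += g[:, None] * v[None, :]
                    W_in[center] += dv
    vectors = {tok: W_in[index[tok]].copy() for tok, _ in vocab_counts}
    return EmbeddingTable(k=k, vectors=vectors)


# --- the abstract matrix ----------------------------------------------------

@dataclass(frozen=True)
class AbstractMatrix:
    """The m-by-k input representation of one abstract.

    Row i holds the word vector of token i; rows past the true token count
    (padding) and rows of out-of-vocabulary tokens are all zero.
    """

    V: np.ndarray  # float32, shape (m, k)
    source_sequence: TokenSequence


def embedding_matrix(table: EmbeddingTable, vocabulary: Mapping[str, int]) -> np.ndarray:
    """Dense (|vocab|+1, k) matrix aligned to vocabulary ids.

    Row 0 (padding/OOV) is zero; tokens in the vocabulary but absent from
    the table also get zero rows.
    """
    n = max(vocabulary.values(), default=0) + 1
    E = np.zeros((n, table.k), dtype=np.float32)
    for tok, idx in vocabulary.items():
        if tok in table:
            E[idx] = table.vectors[tok]
    E[PAD_ID] = 0.0
    return E


def embed_abstract(
    seq: TokenSequence, table: EmbeddingTable, vocabulary: Mapping[str, int]
) -> AbstractMatrix:
    """Build the abstract matrix V for an encoded token sequence."""
    E = embedding_matrix(table, vocabulary)
    V = E[seq.token_ids]
    return AbstractMatrix(V=V, source_sequence=seq)
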