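"""Synthetic journal-labelled abstract corpora.

Every stage of the pipeline is testable without downloading articles: the
generator emulates a venue-classification corpus as a per-journal unigram
mixture — each document draws its words from its journal's topic vocabulary
with probability ``topic_sharpness`` and from a shared pool otherwise, with
document lengths drawn from a word-count bin distribution shaped like a real
biomedical abstract corpus (mode around 150-200 words, a thin tail past
350). A unigram mixture keeps the Bayes-optimal baseline analytic: at
sharpness 1 the class vocabularies are disjoint and a majority-membership
classifier is perfect, which upper-bounds what the network should approach.

Synthetic journals carry LocatorPlus-style labels and print/electronic ISSN
pairs with valid check digits, so the catalog code paths see realistic
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import PaperRecord

__all__ = [
    "SyntheticSpec",
    "DEFAULT_LENGTH_BINS",
    "DEFAULT_LENGTH_PROBS",
    "generate_corpus",
    "make_fixture_xml",
    "record_to_jats",
    "issn_label_map",
    "imbalanced_preset",
    "issn_check_digit",
]

#: Word-count bins documents are drawn from: [lo, hi) pairs.
DEFAULT_LENGTH_BINS = (
    (20, 50), (50, 100), (100, 150), (150, 200),
    (200, 250), (250, 300), (300, 350), (350, 400),
)

# Bin probabilities shaped like the word-count histogram of a large PMC
# abstract corpus (unimodal, mode in 150-200, ~5% beyond 350 words).
_SHAPE = np.array([25_499, 76_614, 139_420, 227_993, 191_156, 87_597, 46_275, 43_328], float)
DEFAULT_LENGTH_PROBS = tuple(_SHAPE / _SHAPE.sum())


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    ``class_sizes`` supports imbalance ratios up to ~1000:1;
    ``topic_sharpness`` interpolates between fully shared vocabulary (0) and
    disjoint per-class vocabularies (1); ``shared_vocab_fraction`` of the
    vocabulary forms the shared pool, the remainder is split evenly and
    disjointly across classes.
    """

    n_classes: int = 5
    class_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    vocab_size: int = 1000
    topic_sharpness: float = 0.9
    shared_vocab_fraction: float = 0.3
    length_bins: tuple[tuple[int, int], ...] = DEFAULT_LENGTH_BINS
    length_probs: tuple[float, ...] = DEFAULT_LENGTH_PROBS
    seed: int = 0

    def __post_init__(self):
        if len(self.class_sizes) != self.n_classes:
            raise ValueError(
                f"{len(self.class_sizes)} class sizes for n_classes={self.n_classes}"
            )
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must all be >= 1")
        if not 0.0 <= self.topic_sharpness <= 1.0:
            raise ValueError("topic_sharpness must lie in [0, 1]")
        probs = np.asarray(self.length_probs, float)
        if len(probs) != len(self.length_bins) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("length_probs must match length_bins and sum to 1")


def issn_check_digit(seven_digits: str) -> str:
    """ISSN check character for a 7-digit prefix (mod-11, 'X' for 10)."""
    total = sum(int(d) * w for d, w in zip(seven_digits, range(8, 1, -1)))
    c = (11 - total % 11) % 11
    return "X" if c == 10 else str(c)


def _issn(rng: np.random.Generator) -> str:
    digits = "".join(str(d) for d in rng.integers(0, 10, size=7))
    return f"{digits[:4]}-{digits[4:]}{issn_check_digit(digits)}"


def generate_corpus(spec: SyntheticSpec) -> tuple[list[PaperRecord], dict[str, list[str]]]:
    """Sample a labelled corpus from the per-class unigram mixture.

    Returns the records and the ground-truth class-specific vocabularies
    (journal_label -> token list). Deterministic per ``spec.seed``. Raises
    ``ValueError`` if the vocabulary is too small to give every class a
    non-empty private sub-vocabulary.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_classes
    n_shared = int(round(spec.shared_vocab_fraction * spec.vocab_size))
    n_private = spec.vocab_size - n_shared
    if n_private < T:
        raise ValueError(
            f"vocab_size={spec.vocab_size} leaves {n_private} private tokens for "
            f"{T} disjoint class vocabularies"
        )
    tokens = [f"lexeme{i:05d}" for i in range(spec.vocab_size)]
    shared_pool = tokens[:n_shared]
    per_class = n_private // T
    labels = [f"NLM{c:06d}" for c in range(T)]
    class_vocab = {
        labels[c]: tokens[n_shared + c * per_class : n_shared + (c + 1) * per_class]
        for c in range(T)
    }

    bins = np.asarray(spec.length_bins)
    probs = np.asarray(spec.length_probs, float)
    records: list[PaperRecord] = []
    pid = 0
    for c, size in enumerate(spec.class_sizes):
        label = labels[c]
        cvocab = np.asarray(class_vocab[label])
        pool = np.asarray(shared_pool) if shared_pool else cvocab
        sharp = spec.topic_sharpness if shared_pool else 1.0
        issn_p, issn_e = _issn(rng), _issn(rng)
        bin_idx = rng.choice(len(bins), size=size, p=probs)
        lengths = rng.integers(bins[bin_idx, 0], bins[bin_idx, 1])
        years = rng.integers(2007, 2017, size=size)
        months = rng.integers(1, 13, size=size)
        for d in range(size):
            L = int(lengths[d])
            from_class = rng.random(L) < sharp
            words = np.where(
                from_class,
                cvocab[rng.integers(0, len(cvocab), size=L)],
                pool[rng.integers(0, len(pool), size=L)],
            )
            records.append(
                PaperRecord(
                    paper_id=f"SYN{pid:07d}",
                    abstract_text=" ".join(words),
                    journal_label=label,
                    issn_print=issn_p,
                    issn_electronic=issn_e,
                    pub_year=int(years[d]),
                    pub_month=int(months[d]),
                )
            )
            pid += 1
    return records, class_vocab


def issn_label_map(records: Sequence[PaperRecord]) -> dict[str, str]:
    """ISSN -> journal_label mapping harvested from records (the 'journal list')."""
    mapping: dict[str, str] = {}
    for rec in records:
        for issn in (rec.issn_print, rec.issn_electronic):
            if issn is not None:
                mapping[issn] = rec.journal_label
    return mapping


_JATS_TEMPLATE = """<article>
  <front>
    <journal-meta>
      {issn_elements}
    </journal-meta>
    <article-meta>
      <article-id>{paper_id}</article-id>
      <pub-date><month>{month}</month><year>{year}</year></pub-date>
      {abstract_element}
    </article-meta>
  </front>
</article>
"""


def record_to_jats(record: PaperRecord) -> str:
    """Render a record as a minimal well-formed JATS article document.

    A record with empty abstract text renders without an ``<abstract>``
    element, which is how abstract-less articles appear in the wild.
    """
    from xml.sax.saxutils import escape

    issns = []
    if record.issn_print:
        issns.append(f'<issn pub-type="ppub">{record.issn_print}</issn>')
    if record.issn_electronic:
        issns.append(f'<issn pub-type="epub">{record.issn_electronic}</issn>')
    abstract_element = (
        f"<abstract><p>{escape(record.abstract_text)}</p></abstract>"
        if record.abstract_text
        else ""
    )
    return _JATS_TEMPLATE.format(
        issn_elements="\n      ".join(issns),
        paper_id=escape(record.paper_id),
        month=record.pub_month,
        year=record.pub_year,
        abstract_element=abstract_element,
    )


def make_fixture_xml(records: Sequence[PaperRecord], out_dir) -> list[Path]:
    """Write one JATS article file per record; returns the file paths.

    The files round-trip through ``corpus_io.parse_jats_record`` (with the
    ISSN->label map from :func:`issn_label_map`) back to the original
    abstract, ISSNs and date.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        path = out_dir / f"{rec.paper_id}.xml"
        path.write_text(record_to_jats(rec))
        paths.append(path)
    return paths


def imbalanced_preset(seed: int = 0) -> SyntheticSpec:
    """A desk-scale corpus spanning all four journal size bins.

    Class sizes 120/300 (tiny), 700/1500 (small), 2600 (medium), 10,400
    (large) — about 15,600 documents in total, mirroring the heavy-tailed
    shape of real venue corpora (one dominant mega-journal, many small
    venues) while staying well under 20,000 documents.
    """
    sizes = (120, 300, 700, 1500, 2600, 10_400)
    return SyntheticSpec(
        n_classes=len(sizes),
        class_sizes=sizes,
        vocab_size=4000,
        topic_sharpness=0.9,
        shared_vocab_fraction=0.3,
        seed=seed,
    )
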