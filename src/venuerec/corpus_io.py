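"""Corpus ingestion: JATS XML parsing, inclusion filters, journal catalog, splits.

The corpus pipeline mirrors how PubMed Central bulk packages are curated for
venue-classification work: each article file is parsed for its ``<abstract>``,
``<issn>`` and ``<pub-date>`` fields, abstracts shorter than a character
threshold are dropped, journals with too few surviving papers are dropped,
and both the print and electronic ISSN of a journal are unified under a
single catalog label (the NLM LocatorPlus-style unique journal identifier).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "PaperRecord",
    "Rejection",
    "JournalCatalog",
    "CatalogEntry",
    "CorpusSplit",
    "DEFAULT_DATE_RANGE",
    "SIZE_BIN_EDGES",
    "normalize_whitespace",
    "parse_jats_record",
    "filter_corpus",
    "build_journal_catalog",
    "size_bin_for_count",
    "split_corpus",
    "write_records_jsonl",
    "read_records_jsonl",
]

#: Inclusive (year, month) publication window used by the default corpus filter.
DEFAULT_DATE_RANGE = ((2007, 1), (2017, 4))

#: Journal size-bin boundaries on training-corpus paper counts:
#: tiny 100<=x<=400, small 400<x<=2000, medium 2000<x<=10000, large x>10000.
SIZE_BIN_EDGES = (400, 2000, 10_000)

SIZE_BINS = ("tiny", "small", "medium", "large")


def size_bin_for_count(count: int) -> str:
    """Map a journal's paper count to its size bin (tiny/small/medium/large)."""
    if count <= SIZE_BIN_EDGES[0]:
        return "tiny"
    if count <= SIZE_BIN_EDGES[1]:
        return "small"
    if count <= SIZE_BIN_EDGES[2]:
        return "medium"
    return "large"


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs to single spaces and strip the ends.

    Abstract character counts are taken on this normalized form, so that
    formatting differences between XML sources do not move papers across
    the length threshold.
    """
    return " ".join(text.split())


@dataclass(frozen=True)
class PaperRecord:
    """One article: abstract text, journal label and provenance fields."""

    paper_id: str
    abstract_text: str
    journal_label: str
    issn_print: str | None = None
    issn_electronic: str | None = None
    pub_year: int = 0
    pub_month: int = 1  # missing month in the source defaults to January

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: Mapping) -> "PaperRecord":
        return cls(**obj)


@dataclass(frozen=True)
class Rejection:
    """A structured record of why a paper was excluded.

    ``reason`` is machine readable: one of ``no_abstract``, ``short_abstract``,
    ``no_issn``, ``malformed``, ``out_of_date_range``, ``journal_too_small``.
    """

    paper_id: str
    reason: str
    detail: str = ""


PARSE_REASONS = frozenset({"no_abstract", "short_abstract", "no_issn", "malformed"})


def _element_text(el) -> str:
    return normalize_whitespace("".join(el.itertext()))


def parse_jats_record(
    xml_text: str | bytes,
    *,
    min_abstract_chars: int = 200,
    issn_to_label: Mapping[str, str] | None = None,
) -> PaperRecord | Rejection:
    """Parse a single JATS article document into a :class:`PaperRecord`.

    Extracts the ``<abstract>``, ``<issn>`` (print and electronic) and
    ``<pub-date>`` fields. Papers without an abstract, with an abstract below
    ``min_abstract_chars`` characters (counted after whitespace
    normalization), or without any ISSN are rejected with a machine-readable
    reason code rather than raising.

    Parameters
    ----------
    xml_text:
        The article XML as a string or bytes. Malformed XML yields
        ``Rejection(reason="malformed")``.
    issn_to_label:
        Optional mapping from ISSN to the unique journal identifier
        (LocatorPlus-style). When given, papers whose ISSNs are all absent
        from the mapping are rejected with ``no_issn``; when omitted the
        label is derived from the first available ISSN.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        return Rejection(paper_id="", reason="malformed", detail=str(exc))

    pid_el = root.find(".//article-id")
    paper_id = _element_text(pid_el) if pid_el is not None else ""

    abstract_el = root.find(".//abstract")
    if abstract_el is None:
        return Rejection(paper_id, "no_abstract")
    abstract = _element_text(abstract_el)
    if len(abstract) < min_abstract_chars:
        return Rejection(
            paper_id, "short_abstract", detail=f"{len(abstract)} chars < {min_abstract_chars}"
        )

    issn_print = issn_electronic = None
    for issn_el in root.iter("issn"):
        kind = issn_el.get("pub-type", "")
        value = _element_text(issn_el)
        if not value:
            continue
        if kind in ("epub", "electronic"):
            issn_electronic = value
        else:
            issn_print = value
    if issn_print is None and issn_electronic is None:
        return Rejection(paper_id, "no_issn")

    if issn_to_label is not None:
        label = None
        for issn in (issn_print, issn_electronic):
            if issn is not None and issn in issn_to_label:
                label = issn_to_label[issn]
                break
        if label is None:
            return Rejection(paper_id, "no_issn", detail="ISSN not in journal list")
    else:
        label = f"ISSN:{issn_print or issn_electronic}"

    year, month = 0, 1
    date_el = root.find(".//pub-date")
    if date_el is not None:
        y = date_el.find("year")
        m = date_el.find("month")
        if y is not None and _element_text(y).isdigit():
            year = int(_element_text(y))
        if m is not None and _element_text(m).isdigit():
            month = int(_element_text(m))

    return PaperRecord(
        paper_id=paper_id,
        abstract_text=abstract,
        journal_label=label,
        issn_print=issn_print,
        issn_electronic=issn_electronic,
        pub_year=year,
        pub_month=month,
    )


def filter_corpus(
    records: Sequence[PaperRecord],
    *,
    min_abstract_chars: int = 200,
    min_journal_papers: int = 100,
    date_range: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_DATE_RANGE,
) -> tuple[list[PaperRecord], list[Rejection]]:
    """Apply the corpus inclusion filters; return (kept, rejection log).

    Paper-level filters run first (abstract length, publication window), then
    the journal-size filter is applied once to the surviving per-journal
    counts. Every removed record appears in the rejection log, so
    ``len(kept) + len(rejected) == len(records)`` always holds.
    """
    (y0, m0), (y1, m1) = date_range
    if (y0, m0) > (y1, m1):
        raise ValueError("date_range must be well ordered")

    survivors: list[PaperRecord] = []
    log: list[Rejection] = []
    for rec in records:
        n_chars = len(normalize_whitespace(rec.abstract_text))
        if n_chars < min_abstract_chars:
            log.append(Rejection(rec.paper_id, "short_abstract", f"{n_chars} chars"))
            continue
        if not ((y0, m0) <= (rec.pub_year, rec.pub_month) <= (y1, m1)):
            log.append(
                Rejection(rec.paper_id, "out_of_date_range", f"{rec.pub_year}-{rec.pub_month:02d}")
            )
            continue
        survivors.append(rec)

    counts = Counter(rec.journal_label for rec in survivors)
    kept = []
    for rec in survivors:
        if counts[rec.journal_label] < min_journal_papers:
            log.append(
                Rejection(
                    rec.paper_id,
                    "journal_too_small",
                    f"{rec.journal_label}: {counts[rec.journal_label]} papers",
                )
            )
        else:
            kept.append(rec)
    return kept, log


@dataclass
class CatalogEntry:
    journal_label: str
    paper_count: int
    size_bin: str
    issns: tuple[str, ...] = ()


@dataclass
class JournalCatalog:
    """ISSN -> journal label mapping plus per-journal counts and size bins."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)  # label -> entry
    issn_to_label: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries)

    def size_bin(self, label: str) -> str:
        return self.entries[label].size_bin

    def to_json(self) -> dict:
        return {
            "entries": {lbl: asdict(e) for lbl, e in self.entries.items()},
            "issn_to_label": self.issn_to_label,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "JournalCatalog":
        entries = {
            lbl: CatalogEntry(
                journal_label=e["journal_label"],
                paper_count=e["paper_count"],
                size_bin=e["size_bin"],
                issns=tuple(e["issns"]),
            )
            for lbl, e in obj["entries"].items()
        }
        return cls(entries=entries, issn_to_label=dict(obj["issn_to_label"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "JournalCatalog":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def build_journal_catalog(records: Iterable[PaperRecord]) -> JournalCatalog:
    """Build the journal catalog from filtered records.

    Both the print and the electronic ISSN of a journal map to the same
    label; an ISSN claimed by two different labels raises ``ValueError``
    (ambiguous catalog).
    """
    counts: Counter[str] = Counter()
    issns: dict[str, set[str]] = {}
    issn_owner: dict[str, str] = {}
    for rec in records:
        counts[rec.journal_label] += 1
        bag = issns.setdefault(rec.journal_label, set())
        for issn in (rec.issn_print, rec.issn_electronic):
            if issn is None:
                continue
            owner = issn_owner.setdefault(issn, rec.journal_label)
            if owner != rec.journal_label:
                raise ValueError(
                    f"ambiguous catalog: ISSN {issn} claimed by {owner!r} and {rec.journal_label!r}"
                )
            bag.add(issn)

    catalog = JournalCatalog()
    for label in sorted(counts):
        catalog.entries[label] = CatalogEntry(
            journal_label=label,
            paper_count=counts[label],
            size_bin=size_bin_for_count(counts[label]),
            issns=tuple(sorted(issns[label])),
        )
    catalog.issn_to_label = {issn: lbl for issn, lbl in sorted(issn_owner.items())}
    return catalog


@dataclass
class CorpusSplit:
    train: list[PaperRecord]
    validation: list[PaperRecord]
    test: list[PaperRecord]
    seed: int

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def split_corpus(
    records: Sequence[PaperRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> CorpusSplit:
    """Randomly partition records into train/validation/test sets.

    Deterministic for a fixed seed. Fractions must be positive and sum to 1;
    set sizes honor the fractions to within integer rounding (train and
    validation take the floor, test takes the remainder).
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train : n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val :]]
    return CorpusSplit(train=train, validation=val, test=test, seed=seed)


def write_records_jsonl(records: Iterable[PaperRecord], path) -> None:
    """Write records as newline-delimited JSON (one object per paper)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json(), sort_keys=True) + "\n")


def read_records_jsonl(path) -> list[PaperRecord]:
    with open(path) as fh:
        return [PaperRecord.from_json(json.loads(line)) for line in fh if line.strip()]
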