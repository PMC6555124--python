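"""Top-N recommendation metrics: acc@N, macro/micro precision-recall-F1
over top-N selections, and journal-size-stratified accuracy.

The top-N convention: a recommender emits an ordered label list per sample;
at cutoff N every label in the first N positions counts as predicted. Per
class c, ``tp`` = samples of c whose top-N contains c, ``fn`` = samples of c
whose top-N misses c, ``fp`` = samples of other classes whose top-N
contains c, ``tn`` = the rest. Macro averages treat classes equally; micro
averages sum counts first and therefore favour large classes. At N=1 this
collapses to ordinary single-label classification, where micro precision =
micro recall = micro F1 = accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import JournalCatalog

__all__ = [
    "ClassCounts",
    "PRF",
    "EvalReport",
    "top_n_accuracy",
    "confusion_counts",
    "macro_micro_metrics",
    "stratified_eval",
    "evaluate_rankings",
    "DEFAULT_N_VALUES",
]

DEFAULT_N_VALUES = (1, 3, 5, 10)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float


@dataclass
class ClassCounts:
    """Per-class tp/fp/fn/tn at a fixed cutoff N."""

    n: int  # the cutoff
    n_samples: int
    counts: dict[str, tuple[int, int, int, int]]  # label -> (tp, fp, fn, tn)

    def __getitem__(self, label):
        return self.counts[label]


def _check_lengths(ranked_predictions, labels, N):
    if len(ranked_predictions) != len(labels):
        raise ValueError(
            f"{len(ranked_predictions)} prediction lists vs {len(labels)} labels"
        )
    for preds in ranked_predictions:
        if len(preds) < N:
            raise ValueError(f"a prediction list has {len(preds)} entries, need >= {N}")


def top_n_accuracy(
    ranked_predictions: Sequence[Sequence[str]], labels: Sequence[str], N: int
) -> float:
    """Fraction of samples whose true label is among the first N predictions."""
    _check_lengths(ranked_predictions, labels, N)
    if not labels:
        raise ValueError("no samples")
    hits = sum(1 for preds, y in zip(ranked_predictions, labels) if y in preds[:N])
    return hits / len(labels)


def confusion_counts(
    ranked_predictions: Sequence[Sequence[str]],
    labels: Sequence[str],
    N: int,
    class_labels: Sequence[str] | None = None,
) -> ClassCounts:
    """Per-class tp/fp/fn/tn from top-N selections."""
    _check_lengths(ranked_predictions, labels, N)
    if class_labels is None:
        class_labels = sorted({*labels, *(l for p in ranked_predictions for l in p[:N])})
    n_samples = len(labels)
    counts = {}
    for c in class_labels:
        tp = fp = fn = 0
        for preds, y in zip(ranked_predictions, labels):
            predicted = c in preds[:N]
            if y == c:
                tp += predicted
                fn += not predicted
            else:
                fp += predicted
        tn = n_samples - tp - fp - fn
        counts[c] = (tp, fp, fn, tn)
    return ClassCounts(n=N, n_samples=n_samples, counts=counts)


def _prf(tp: float, fp: float, fn: float) -> PRF:
    # zero-denominator convention: an empty denominator yields 0
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return PRF(precision=prec, recall=rec, f1=f1)


def macro_micro_metrics(counts: ClassCounts) -> tuple[PRF, PRF]:
    """(macro, micro) precision/recall/F1 from per-class counts.

    Macro is the unweighted mean of the per-class precision, recall and F1
    (each class's F1 is the harmonic mean of its own precision and recall);
    a class whose precision (or recall) denominator is empty contributes 0.
    Micro metrics come from the summed tp/fp/fn counts.
    """
    if not counts.counts:
        raise ValueError("no classes")
    per_class = [_prf(tp, fp, fn) for tp, fp, fn, _ in counts.counts.values()]
    macro = PRF(
        precision=float(np.mean([m.precision for m in per_class])),
        recall=float(np.mean([m.recall for m in per_class])),
        f1=float(np.mean([m.f1 for m in per_class])),
    )

    tp = sum(c[0] for c in counts.counts.values())
    fp = sum(c[1] for c in counts.counts.values())
    fn = sum(c[2] for c in counts.counts.values())
    micro = _prf(tp, fp, fn)
    return macro, micro


def stratified_eval(
    ranked_predictions: Sequence[Sequence[str]],
    labels: Sequence[str],
    catalog: JournalCatalog,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
) -> dict[str, dict]:
    """acc@N per journal size bin (binned by the TRUE journal's catalog count).

    Returns ``{bin: {"paper_count": int, "acc_at": {N: acc}}}`` for every
    size bin with at least one test sample. A label missing from the catalog
    raises ``KeyError``.
    """
    for y in labels:
        if y not in catalog.entries:
            raise KeyError(f"label {y!r} has no catalog entry (size bin unknown)")
    groups: dict[str, list[int]] = {}
    for i, y in enumerate(labels):
        groups.setdefault(catalog.size_bin(y), []).append(i)
    out = {}
    for size_bin in sorted(groups):
        idx = groups[size_bin]
        preds = [ranked_predictions[i] for i in idx]
        ys = [labels[i] for i in idx]
        out[size_bin] = {
            "paper_count": len(idx),
            "acc_at": {int(N): top_n_accuracy(preds, ys, N) for N in n_values},
        }
    return out


@dataclass
class EvalReport:
    """Full evaluation of ranked predictions at the default cutoffs."""

    n_samples: int
    acc_at: dict[int, float]
    macro: dict[int, PRF]
    micro: dict[int, PRF]
    strata: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "acc_at": {str(k): v for k, v in self.acc_at.items()},
            "macro": {str(k): vars(v) for k, v in self.macro.items()},
            "micro": {str(k): vars(v) for k, v in self.micro.items()},
            "strata": self.strata,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["metric\tN\tvalue"]
        for N, v in sorted(self.acc_at.items()):
            lines.append(f"acc\t{N}\t{v:.4f}")
        for kind, table in (("macro", self.macro), ("micro", self.micro)):
            for N, prf in sorted(table.items()):
                lines.append(f"{kind}_precision\t{N}\t{prf.precision:.4f}")
                lines.append(f"{kind}_recall\t{N}\t{prf.recall:.4f}")
                lines.append(f"{kind}_f1\t{N}\t{prf.f1:.4f}")
        for size_bin, entry in sorted(self.strata.items()):
            for N, v in sorted(entry["acc_at"].items()):
                lines.append(f"acc[{size_bin}]\t{N}\t{v:.4f}")
        return "\n".join(lines) + "\n"


def evaluate_rankings(
    ranked_predictions: Sequence[Sequence[str]],
    labels: Sequence[str],
    catalog: JournalCatalog | None = None,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    class_labels: Sequence[str] | None = None,
) -> EvalReport:
    """acc@N, macro/micro metrics, and (with a catalog) size-stratified accuracy."""
    n_values = [int(N) for N in n_values]
    acc_at = {N: top_n_accuracy(ranked_predictions, labels, N) for N in n_values}
    macro, micro = {}, {}
    for N in n_values:
        counts = confusion_counts(ranked_predictions, labels, N, class_labels=class_labels)
        macro[N], micro[N] = macro_micro_metrics(counts)
    strata = (
        stratified_eval(ranked_predictions, labels, catalog, n_values)
        if catalog is not None
        else {}
    )
    return EvalReport(
        n_samples=len(labels), acc_at=acc_at, macro=macro, micro=micro, strata=strata
    )
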