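"""Top-N accuracy, confusion counts, macro/micro metrics, stratified accuracy.

Independent oracles: brute-force enumeration of per-class counts on toy
prediction tables, hand-computed macro/micro values, and scikit-learn's
metrics at N=1 (where top-N selection reduces to single-label
classification).
"""

import numpy as np
import pytest

from venuerec.corpus_io import PaperRecord, build_journal_catalog
from venuerec.evaluation import (
    ClassCounts,
    confusion_counts,
    evaluate_rankings,
    macro_micro_metrics,
    stratified_eval,
    top_n_accuracy,
)


def brute_force_counts(ranked, labels, N, classes):
    """Definition-level enumeration of tp/fp/fn/tn per class."""
    out = {}
    for c in classes:
        tp = sum(1 for p, y in zip(ranked, labels) if y == c and c in p[:N])
        fn = sum(1 for p, y in zip(ranked, labels) if y == c and c not in p[:N])
        fp = sum(1 for p, y in zip(ranked, labels) if y != c and c in p[:N])
        tn = sum(1 for p, y in zip(ranked, labels) if y != c and c not in p[:N])
        out[c] = (tp, fp, fn, tn)
    return out


def random_rankings(rng, n_samples, classes):
    ranked = [list(rng.permutation(classes)) for _ in range(n_samples)]
    labels = [str(rng.choice(classes)) for _ in range(n_samples)]
    return ranked, labels


class TestTopNAccuracy:
    def test_single_sample(self):
        assert top_n_accuracy([["A", "B"]], ["A"], 1) == 1.0

    def test_truth_ranked_third(self):
        ranked = [["B", "C", "A"]]
        assert top_n_accuracy(ranked, ["A"], 1) == 0.0
        assert top_n_accuracy(ranked, ["A"], 3) == 1.0

    def test_non_decreasing_in_n(self):
        rng = np.random.default_rng(0)
        ranked, labels = random_rankings(rng, 50, ["A", "B", "C", "D", "E"])
        accs = [top_n_accuracy(ranked, labels, N) for N in range(1, 6)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0  # N = number of classes captures every truth

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            top_n_accuracy([["A"]], ["A", "B"], 1)
        with pytest.raises(ValueError):
            top_n_accuracy([["A"]], ["A"], 2)

    def test_agrees_with_sklearn_top_k(self):
        from sklearn.metrics import top_k_accuracy_score

        rng = np.random.default_rng(4)
        classes = ["A", "B", "C", "D"]
        S = rng.dirichlet(np.ones(4), size=40)
        y = rng.integers(0, 4, size=40)
        order = np.argsort(-S, axis=1, kind="stable")
        ranked = [[classes[j] for j in row] for row in order]
        labels = [classes[i] for i in y]
        for N in (1, 2, 3):
            ours = top_n_accuracy(ranked, labels, N)
            theirs = top_k_accuracy_score(y, S, k=N, labels=np.arange(4))
            assert np.isclose(ours, theirs)


class TestConfusionCounts:
    def test_perfect_top1_has_no_errors(self):
        ranked = [["A", "B"], ["B", "A"], ["A", "B"]]
        labels = ["A", "B", "A"]
        counts = confusion_counts(ranked, labels, 1)
        for tp, fp, fn, tn in counts.counts.values():
            assert fp == 0 and fn == 0

    def test_partition_per_class(self):
        rng = np.random.default_rng(7)
        classes = ["A", "B", "C"]
        ranked, labels = random_rankings(rng, 30, classes)
        for N in (1, 2, 3):
            counts = confusion_counts(ranked, labels, N, class_labels=classes)
            for tp, fp, fn, tn in counts.counts.values():
                assert tp + fp + fn + tn == 30

    def test_matches_brute_force_enumeration(self):
        classes = ["A", "B", "C"]
        ranked = [
            ["A", "B", "C"], ["B", "A", "C"], ["C", "B", "A"],
            ["A", "C", "B"], ["B", "C", "A"], ["C", "A", "B"],
        ]
        labels = ["A", "A", "B", "B", "C", "C"]
        for N in (1, 2, 3):
            got = confusion_counts(ranked, labels, N, class_labels=classes)
            assert got.counts == brute_force_counts(ranked, labels, N, classes)


class TestMacroMicro:
    def test_all_correct_gives_ones(self):
        ranked = [["A", "B"], ["B", "A"]]
        counts = confusion_counts(ranked, ["A", "B"], 1)
        macro, micro = macro_micro_metrics(counts)
        for prf in (macro, micro):
            assert prf.precision == prf.recall == prf.f1 == 1.0

    def test_two_class_hand_computed_values(self):
        # per class (tp, fp, fn): A=(3,1,2), B=(1,3,1)
        counts = ClassCounts(
            n=1, n_samples=7,
            counts={"A": (3, 1, 2, 1), "B": (1, 3, 1, 2)},
        )
        macro, micro = macro_micro_metrics(counts)
        # A: P=3/4, R=3/5, F1=2/3 ; B: P=1/4, R=1/2, F1=1/3
        assert np.isclose(macro.precision, 0.5)
        assert np.isclose(macro.recall, 0.55)
        assert np.isclose(macro.f1, 0.5)
        # pooled: tp=4, fp=4, fn=3
        assert np.isclose(micro.precision, 0.5)
        assert np.isclose(micro.recall, 4 / 7)
        assert np.isclose(micro.f1, 2 * 0.5 * (4 / 7) / (0.5 + 4 / 7))

    def test_micro_collapses_to_accuracy_at_top1(self):
        rng = np.random.default_rng(11)
        classes = ["A", "B", "C", "D"]
        ranked, labels = random_rankings(rng, 60, classes)
        counts = confusion_counts(ranked, labels, 1, class_labels=classes)
        _, micro = macro_micro_metrics(counts)
        acc = top_n_accuracy(ranked, labels, 1)
        assert micro.precision == micro.recall == micro.f1 == acc

    def test_agrees_with_sklearn_at_top1(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(13)
        classes = ["A", "B", "C", "D"]
        ranked, labels = random_rankings(rng, 80, classes)
        top1 = [p[0] for p in ranked]
        counts = confusion_counts(ranked, labels, 1, class_labels=classes)
        macro, micro = macro_micro_metrics(counts)
        for avg, ours in (("macro", macro), ("micro", micro)):
            p, r, f, _ = precision_recall_fscore_support(
                labels, top1, labels=classes, average=avg, zero_division=0
            )
            assert np.isclose(ours.precision, p)
            assert np.isclose(ours.recall, r)
            assert np.isclose(ours.f1, f)

    def test_macro_recall_is_one_at_n_equals_t(self):
        rng = np.random.default_rng(17)
        classes = ["A", "B", "C"]
        ranked, labels = random_rankings(rng, 20, classes)
        counts = confusion_counts(ranked, labels, 3, class_labels=classes)
        macro, _ = macro_micro_metrics(counts)
        assert macro.recall == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            macro_micro_metrics(ClassCounts(n=1, n_samples=0, counts={}))


def _catalog_with_bins():
    """Two journals: 'big' lands in the small bin, 'rare' in the tiny bin."""
    records = [
        PaperRecord(f"b{i}", "x" * 250, "big", "1234-5679", None, 2010, 1)
        for i in range(500)
    ]
    records += [
        PaperRecord(f"r{i}", "x" * 250, "rare", "2434-561X", None, 2010, 1)
        for i in range(100)
    ]
    return build_journal_catalog(records)


class TestStratified:
    def test_two_bin_fixture_exact_values(self):
        catalog = _catalog_with_bins()
        ranked = [
            ["big", "rare"], ["big", "rare"], ["rare", "big"],  # big: 2/3 at top-1
            ["rare", "big"], ["big", "rare"],                     # rare: 1/2 at top-1
        ]
        labels = ["big", "big", "big", "rare", "rare"]
        strata = stratified_eval(ranked, labels, catalog, n_values=(1, 2))
        assert strata["small"]["paper_count"] == 3
        assert strata["tiny"]["paper_count"] == 2
        assert np.isclose(strata["small"]["acc_at"][1], 2 / 3)
        assert np.isclose(strata["tiny"]["acc_at"][1], 1 / 2)
        assert strata["small"]["acc_at"][2] == strata["tiny"]["acc_at"][2] == 1.0

    def test_single_bin_equals_overall(self):
        catalog = _catalog_with_bins()
        ranked = [["big", "rare"], ["rare", "big"], ["big", "rare"]]
        labels = ["big", "big", "big"]
        strata = stratified_eval(ranked, labels, catalog, n_values=(1,))
        assert strata["small"]["acc_at"][1] == top_n_accuracy(ranked, labels, 1)

    def test_weighted_mean_partition_identity(self):
        catalog = _catalog_with_bins()
        rng = np.random.default_rng(23)
        ranked, labels = random_rankings(rng, 40, ["big", "rare"])
        strata = stratified_eval(ranked, labels, catalog, n_values=(1, 2))
        for N in (1, 2):
            weighted = sum(e["paper_count"] * e["acc_at"][N] for e in strata.values())
            total_correct = top_n_accuracy(ranked, labels, N) * len(labels)
            assert np.isclose(weighted, total_correct)

    def test_unknown_label_rejected(self):
        catalog = _catalog_with_bins()
        with pytest.raises(KeyError):
            stratified_eval([["big"]], ["mystery"], catalog, n_values=(1,))


def test_report_assembly_and_serialization(tmp_path):
    catalog = _catalog_with_bins()
    rng = np.random.default_rng(29)
    ranked, labels = random_rankings(rng, 30, ["big", "rare"])
    report = evaluate_rankings(ranked, labels, catalog=catalog, n_values=(1, 2))
    assert report.n_samples == 30
    assert report.acc_at[1] <= report.acc_at[2]
    assert report.micro[1].precision == report.acc_at[1]
    path = tmp_path / "report.json"
    report.save(path)
    import json

    loaded = json.loads(path.read_text())
    assert np.isclose(loaded["acc_at"]["1"], report.acc_at[1])
    assert "tiny" in loaded["strata"] and "small" in loaded["strata"]
    tsv = report.to_tsv()
    assert "acc\t1\t" in tsv and "macro_f1\t2\t" in tsv
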