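"""Confusion-matrix arithmetic, checked against the published validation
tables and against independent recomputation (brute force and
scikit-learn)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

from seedlingscreen.evaluation import (
    LABELS,
    ClassCounts,
    accuracy,
    confusion,
    format_percent,
    metrics,
    misclassified,
    per_class_counts,
    report,
)


def _labels_from_cm(cm):
    """Expand a predicted×true count matrix into label sequences."""
    true, pred = [], []
    for p in range(3):
        for t in range(3):
            true += [LABELS[t]] * int(cm[p, t])
            pred += [LABELS[p]] * int(cm[p, t])
    return true, pred


def test_confusion_diagonal_for_perfect_predictions():
    labels = ["healthy"] * 3 + ["unhealthy"] * 2 + ["none"]
    cm = confusion(labels, labels)
    np.testing.assert_array_equal(cm, np.diag([3, 2, 1]))


def test_confusion_single_predicted_class():
    cm = confusion(["healthy", "unhealthy", "none"], ["none"] * 3)
    assert cm[2].tolist() == [1, 1, 1]
    assert cm[:2].sum() == 0


def test_confusion_reconstructs_validation_matrix(cm_network):
    true, pred = _labels_from_cm(cm_network)
    np.testing.assert_array_equal(confusion(true, pred), cm_network)


def test_confusion_errors():
    with pytest.raises(ValueError):
        confusion(["healthy"], ["healthy", "none"])
    with pytest.raises(ValueError):
        confusion(["healthy"], ["weird"])


@pytest.mark.parametrize(
    "which,label,expected",
    [
        ("network", "healthy", (439, 11, 12, 438)),
        ("network", "unhealthy", (138, 12, 11, 739)),
        ("network", "none", (300, 0, 0, 600)),
        ("physical", "healthy", (399, 41, 55, 405)),
        ("physical", "unhealthy", (105, 55, 41, 699)),
        ("physical", "none", (300, 0, 0, 600)),
    ],
)
def test_per_class_counts_match_published_tables(
    which, label, expected, cm_network, cm_physical
):
    cm = cm_network if which == "network" else cm_physical
    counts = per_class_counts(cm, label)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == expected
    assert counts.total == int(cm.sum())


def test_metrics_on_published_counts():
    m = metrics(ClassCounts(tp=439, fp=11, fn=12, tn=438))
    assert m.precision == pytest.approx(0.9756, abs=5e-5)
    assert m.recall == pytest.approx(0.9734, abs=5e-5)
    assert m.f1 == pytest.approx(878 / 901)
    m = metrics(ClassCounts(tp=138, fp=12, fn=11, tn=739))
    assert m.precision == pytest.approx(0.92)
    assert m.recall == pytest.approx(0.9262, abs=5e-5)
    assert m.f1 == pytest.approx(0.9231, abs=5e-5)
    m = metrics(ClassCounts(tp=300, fp=0, fn=0, tn=600))
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


def test_accuracy_and_misclassified(cm_network, cm_physical):
    assert accuracy(cm_network) == pytest.approx(877 / 900)
    assert misclassified(cm_network) == 23
    assert accuracy(cm_physical) == pytest.approx(804 / 900)
    assert misclassified(cm_physical) == 96
    assert accuracy(np.diag([5, 5, 5])) == 1.0
    assert misclassified(np.diag([5, 5, 5])) == 0


def test_accuracy_empty_matrix_rejected():
    with pytest.raises(ValueError):
        accuracy(np.zeros((3, 3), dtype=int))


def test_zero_denominator_convention():
    m = metrics(ClassCounts(tp=0, fp=0, fn=0, tn=10))
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
    assert m.undefined


@given(st.lists(st.integers(0, 40), min_size=9, max_size=9))
def test_count_and_micro_average_invariants(entries):
    cm = np.array(entries).reshape(3, 3)
    total = int(cm.sum())
    if total == 0:
        return
    for label in LABELS:
        assert per_class_counts(cm, label).total == total
    # micro-averaged recall equals accuracy for a square count matrix
    tps = sum(per_class_counts(cm, l).tp for l in LABELS)
    fns = sum(per_class_counts(cm, l).fn for l in LABELS)
    assert tps / (tps + fns) == pytest.approx(accuracy(cm))


def test_metrics_agree_with_bruteforce_and_sklearn(rng):
    for _ in range(100):
        n = int(rng.integers(3, 60))
        true = [LABELS[i] for i in rng.integers(0, 3, size=n)]
        pred = [LABELS[i] for i in rng.integers(0, 3, size=n)]
        cm = confusion(true, pred)
        # brute force straight from the label lists
        for label in LABELS:
            tp = sum(t == p == label for t, p in zip(true, pred))
            fp = sum(p == label and t != label for t, p in zip(true, pred))
            fn = sum(t == label and p != label for t, p in zip(true, pred))
            counts = per_class_counts(cm, label)
            assert (counts.tp, counts.fp, counts.fn) == (tp, fp, fn)
        prec, rec, f1, _ = precision_recall_fscore_support(
            true, pred, labels=list(LABELS), zero_division=0
        )
        for i, label in enumerate(LABELS):
            m = metrics(per_class_counts(cm, label))
            assert m.precision == pytest.approx(prec[i])
            assert m.recall == pytest.approx(rec[i])
            assert m.f1 == pytest.approx(f1[i])
        assert accuracy(cm) == pytest.approx(np.mean([t == p for t, p in zip(true, pred)]))


@pytest.mark.parametrize(
    "fraction,text",
    [
        (0.92, "92%"),
        (0.9756, "97.56%"),
        (0.9262, "92.62%"),
        (1.0, "100%"),
        (0.89333333, "89.33%"),
        (0.0, "0%"),
        (0.686275, "68.63%"),
    ],
)
def test_percent_rendering(fraction, text):
    assert format_percent(fraction) == text


def test_report_roundtrip(cm_network):
    true, pred = _labels_from_cm(cm_network)
    rep = report(true, pred)
    assert rep["accuracy_pct"] == "97.44%"
    assert rep["misclassified"] == 23
    assert rep["per_class"]["unhealthy"]["precision_pct"] == "92%"
    assert rep["per_class"]["none"]["f1_pct"] == "100%"
    assert rep["total"] == 900
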