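"""Metrics: truncation convention, PRF oracle, matching oracle, k-fold."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from whalescan import (
    BBox,
    ConfusionMatrix3,
    Detection,
    box_iou,
    f1_improvement_points,
    kfold_evaluate,
    match_detections,
    misclassification_rates,
    posture_detectability,
    precision_recall_f1,
    truncate_pct,
)


# ---------------------------------------------------------------------------
# Truncated-percentage convention
# ---------------------------------------------------------------------------


def test_truncate_pct_reference_values():
    assert truncate_pct(13 / 68) == 19.11
    assert truncate_pct(1 / 68) == 1.47
    assert truncate_pct(14 / 68) == 20.58
    assert truncate_pct(4 / 400) == 1.00
    assert truncate_pct(9 / 400) == 2.25
    assert truncate_pct(54 / 67) == 80.59
    assert truncate_pct(54 / 68) == 79.41


def test_truncate_pct_truncates_not_rounds():
    assert truncate_pct(0.12999) == 12.99
    assert truncate_pct(0.0001999) == 0.01
    assert truncate_pct(1.0) == 100.0
    assert truncate_pct(0.0) == 0.0


def test_truncate_pct_matches_integer_oracle():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        num = int(rng.integers(0, 500))
        den = int(rng.integers(1, 500))
        frac = Fraction(num, den)
        expected = (frac.numerator * 10000 // frac.denominator) / 100.0
        assert truncate_pct(num / den) == expected


# ---------------------------------------------------------------------------
# Precision / recall / F1
# ---------------------------------------------------------------------------


def test_prf_zero_counts_are_zero_not_nan():
    m = precision_recall_f1(0, 0, 0)
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
    assert precision_recall_f1(0, 5, 0).precision == 0.0
    assert precision_recall_f1(0, 0, 5).recall == 0.0


def test_prf_rejects_negative_counts():
    with pytest.raises(ValueError):
        precision_recall_f1(-1, 0, 0)


def test_prf_reference_counting_case():
    """tp=54 fp=13 fn=14: precision 80.59%, recall 79.41%, F1 80.00%."""
    m = precision_recall_f1(54, 13, 14)
    assert m.precision_pct == 80.59
    assert m.recall_pct == 79.41
    assert m.f1_pct == 80.00


def test_prf_matches_exact_fraction_oracle():
    rng = np.random.default_rng(2)
    for _ in range(1000):
        tp, fp, fn = (int(x) for x in rng.integers(0, 60, 3))
        m = precision_recall_f1(tp, fp, fn)
        p = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
        r = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
        f1 = 2 * p * r / (p + r) if p + r else Fraction(0)
        assert m.precision == pytest.approx(float(p))
        assert m.recall == pytest.approx(float(r))
        assert m.f1 == pytest.approx(float(f1))
        # F1 is also 2tp / (2tp + fp + fn)
        if 2 * tp + fp + fn:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


def test_f1_improvement_points():
    assert f1_improvement_points(78.0, 42.0) == 36.0


# ---------------------------------------------------------------------------
# Confusion matrix and misclassification rates
# ---------------------------------------------------------------------------


def test_confusion_from_labels_and_class_counts():
    true = ["whale", "whale", "ship", "water_rock", "water_rock", "whale"]
    pred = ["whale", "water_rock", "ship", "water_rock", "whale", "whale"]
    cm = ConfusionMatrix3.from_labels(true, pred)
    assert cm.total == 6
    assert cm.row_total("whale") == 3
    tp, fp, fn = cm.class_counts("whale")
    assert (tp, fp, fn) == (2, 1, 1)


def test_confusion_validation():
    with pytest.raises(ValueError):
        ConfusionMatrix3(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        ConfusionMatrix3(np.full((3, 3), -1))


def test_misclassification_rates_whale_row():
    """Whale row (54 correct; 1 to ship; 13 to water): 1.47 / 19.11 / 20.58."""
    counts = np.array([[54, 1, 13], [0, 100, 0], [0, 0, 100]])
    rates = misclassification_rates(ConfusionMatrix3(counts), "whale")
    assert rates["ship"] == 1.47
    assert rates["water_rock"] == 19.11
    assert rates["total"] == 20.58


def test_misclassification_rates_confuser_rows():
    counts = np.array([[10, 0, 0], [9, 391, 0], [4, 0, 396]])
    assert misclassification_rates(ConfusionMatrix3(counts), "ship")["whale"] == 2.25
    assert misclassification_rates(ConfusionMatrix3(counts), "water_rock")["whale"] == 1.00


def test_misclassification_rates_empty_row_raises():
    counts = np.zeros((3, 3), dtype=int)
    with pytest.raises(ValueError):
        misclassification_rates(ConfusionMatrix3(counts), "whale")


# ---------------------------------------------------------------------------
# Detection matching
# ---------------------------------------------------------------------------


def _boxes(specs, scored=False):
    out = []
    for k, (x0, y0, x1, y1, *rest) in enumerate(specs):
        score = rest[0] if rest else 1.0
        b = BBox(x0, y0, x1, y1, class_label="whale", score=score if scored else None)
        out.append(Detection(box=b, score=score) if scored else b)
    return out


def _max_matching_oracle(preds, gts, thr):
    """Exhaustive maximum matching size for small instances: try every
    injective assignment of predictions to ground truth and count the
    feasible pairs it realizes."""
    n, m = len(preds), len(gts)
    feasible = [[box_iou(p, g) >= thr for g in gts] for p in preds]
    k = min(n, m)
    best = 0
    for pred_idx in itertools.permutations(range(n), k):
        for gt_idx in itertools.permutations(range(m), k):
            count = sum(1 for i, j in zip(pred_idx, gt_idx) if feasible[i][j])
            best = max(best, count)
    return best


def test_match_counts_conserved_and_optimal_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(60):
        n_pred = int(rng.integers(0, 5))
        n_gt = int(rng.integers(0, 5))
        preds, gts = [], []
        for _ in range(n_pred):
            x0, y0 = rng.uniform(0, 30, 2)
            preds.append(
                Detection(
                    box=BBox(x0, y0, x0 + rng.uniform(2, 15), y0 + rng.uniform(2, 15)),
                    score=float(rng.uniform(0, 1)),
                )
            )
        for _ in range(n_gt):
            x0, y0 = rng.uniform(0, 30, 2)
            gts.append(BBox(x0, y0, x0 + rng.uniform(2, 15), y0 + rng.uniform(2, 15)))
        thr = float(rng.uniform(0.1, 0.6))
        greedy = match_detections(preds, gts, iou_threshold=thr, method="greedy")
        optimal = match_detections(preds, gts, iou_threshold=thr, method="optimal")
        for res in (greedy, optimal):
            assert res.tp + res.fp == n_pred
            assert res.tp + res.fn == n_gt
            for pair in res.pairs:
                assert pair.iou >= thr
                assert pair.iou == pytest.approx(box_iou(pair.pred, pair.gt))
        assert greedy.tp <= optimal.tp
        if n_pred and n_gt:
            oracle = _max_matching_oracle([p.box for p in preds], gts, thr)
            assert optimal.tp == oracle


def test_greedy_can_undershoot_optimal():
    gts = _boxes([(0, 0, 10, 10), (8, 0, 18, 10)])
    preds = _boxes([(2, 0, 12, 10, 0.9), (0, 0, 10, 10, 0.5)], scored=True)
    greedy = match_detections(preds, gts, iou_threshold=0.2, method="greedy")
    optimal = match_detections(preds, gts, iou_threshold=0.2, method="optimal")
    assert greedy.tp == 1
    assert optimal.tp == 2


def test_match_no_double_assignment():
    gts = _boxes([(0, 0, 10, 10)])
    preds = _boxes([(0, 0, 10, 10, 0.9), (1, 1, 11, 11, 0.8)], scored=True)
    res = match_detections(preds, gts, iou_threshold=0.3)
    assert res.tp == 1 and res.fp == 1 and res.fn == 0


def test_match_validation():
    with pytest.raises(ValueError):
        match_detections([], [], iou_threshold=0.0)
    with pytest.raises(ValueError):
        match_detections([], [], method="fancy")


# ---------------------------------------------------------------------------
# Posture-stratified detectability
# ---------------------------------------------------------------------------


def test_posture_detectability_from_pairs():
    records = [
        ("logging", True),
        ("logging", True),
        ("logging", False),
        ("submerged", False),
        ("submerged", False),
        (None, True),  # untagged: excluded
    ]
    frame = posture_detectability(records)
    assert list(frame["posture"]) == ["logging", "submerged"]
    logging_row = frame[frame.posture == "logging"].iloc[0]
    assert logging_row.detected == 2 and logging_row.missed == 1
    assert logging_row.detection_rate_pct == truncate_pct(2 / 3)
    assert frame[frame.posture == "submerged"].iloc[0].detection_rate_pct == 0.0


def test_posture_detectability_from_mapping():
    frame = posture_detectability(
        {"blowing": {"detected": 4, "missed": 1}, "spyhopping": {"detected": 1, "missed": 3}}
    )
    assert list(frame["posture"]) == ["blowing", "spyhopping"]
    assert frame.iloc[0].detection_rate_pct == 80.0
    assert frame.iloc[1].detection_rate_pct == 25.0


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


class _ToyDataset:
    def __init__(self, labels):
        self.labels = labels


def test_kfold_folds_disjoint_exhaustive_stratified():
    labels = ["whale"] * 10 + ["ship"] * 10 + ["water_rock"] * 10
    seen = []

    def factory(ds, train_idx, test_idx):
        assert set(train_idx).isdisjoint(test_idx)
        assert sorted(train_idx + test_idx) == list(range(30))
        # stratification: each fold holds 2 of each class
        for cls in ("whale", "ship", "water_rock"):
            assert sum(1 for i in test_idx if ds.labels[i] == cls) == 2
        seen.extend(test_idx)
        return {"f1": 0.5 + 0.1 * len(seen) / 30}

    result = kfold_evaluate(_ToyDataset(labels), 5, factory, seed=0)
    assert sorted(seen) == list(range(30))
    assert len(result.per_fold) == 5
    assert result.mean["f1"] == pytest.approx(np.mean([r["f1"] for r in result.per_fold]))
    assert len(result.fold_of) == 30 and set(result.fold_of) == set(range(5))


def test_kfold_deterministic_given_seed():
    labels = (["whale"] * 6 + ["ship"] * 6 + ["water_rock"] * 6)
    factory = lambda ds, tr, te: {"f1": float(len(te))}  # noqa: E731
    a = kfold_evaluate(_ToyDataset(labels), 3, factory, seed=7)
    b = kfold_evaluate(_ToyDataset(labels), 3, factory, seed=7)
    assert a.fold_of == b.fold_of


def test_kfold_validation():
    with pytest.raises(ValueError):
        kfold_evaluate(_ToyDataset(["whale"] * 4), 1, lambda *a: {})
    with pytest.raises(ValueError):
        kfold_evaluate(_ToyDataset(["whale"] * 2), 5, lambda *a: {})
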