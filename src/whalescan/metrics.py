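"""Evaluation suite: confusion matrices, precision/recall/F1, IoU matching,
posture-stratified detectability, k-fold cross-validation and two-step
versus baseline comparison.

Percentages follow the survey-reporting convention of truncating (not
rounding) at two decimals: 14/68 prints as 20.58%, 13/68 as 19.11%.

Precision (positive predictive value) is TP/(TP+FP), sensitivity (recall)
is TP/(TP+FN), and F1 is their harmonic mean; degenerate 0/0 cases are
defined as 0 so empty classes never produce undefined metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .scenes import CLASS_ORDER, BBox, box_iou

logger = logging.getLogger("whalescan")


def truncate_pct(fraction: float) -> float:
    """Express a fraction as a percentage truncated at two decimals."""
    return math.floor(fraction * 10000.0 + 1e-9) / 100.0


# ---------------------------------------------------------------------------
# Class-level metrics
# ---------------------------------------------------------------------------


@dataclass
class ClassMetrics:
    """Precision / recall / F1 with their defining counts."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float

    @property
    def precision_pct(self) -> float:
        return truncate_pct(self.precision)

    @property
    def recall_pct(self) -> float:
        return truncate_pct(self.recall)

    @property
    def f1_pct(self) -> float:
        return truncate_pct(self.f1)


def precision_recall_f1(tp: int, fp: int, fn: int) -> ClassMetrics:
    """Positive predictive value, sensitivity and F1 from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return ClassMetrics(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# Three-class confusion matrix
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix3:
    """3x3 confusion counts; rows = true class, columns = predicted class,
    in the fixed order (whale, ship, water_rock)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, true_labels: Sequence[str], pred_labels: Sequence[str]) -> "ConfusionMatrix3":
        counts = np.zeros((3, 3), dtype=np.int64)
        for t, p in zip(true_labels, pred_labels, strict=True):
            counts[CLASS_ORDER.index(t), CLASS_ORDER.index(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, true_class: str) -> int:
        return int(self.counts[CLASS_ORDER.index(true_class)].sum())

    def class_counts(self, label: str) -> tuple[int, int, int]:
        """(tp, fp, fn) for one class, one-vs-rest."""
        i = CLASS_ORDER.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        return tp, fp, fn

    def class_metrics(self, label: str) -> ClassMetrics:
        return precision_recall_f1(*self.class_counts(label))

    def macro_f1(self) -> float:
        return float(np.mean([self.class_metrics(c).f1 for c in CLASS_ORDER]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))


def misclassification_rates(confusion: ConfusionMatrix3, true_class: str) -> dict[str, float]:
    """Off-diagonal rates (%) for one true class, truncated at 2 decimals.

    Returns one entry per wrong predicted class plus ``"total"``, the
    truncated percentage of all misclassified members of the class.
    """
    i = CLASS_ORDER.index(true_class)
    row = confusion.counts[i]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"no ground-truth members of class {true_class!r}: rate undefined")
    out: dict[str, float] = {}
    wrong = 0
    for j, pred in enumerate(CLASS_ORDER):
        if j == i:
            continue
        out[pred] = truncate_pct(row[j] / total)
        wrong += int(row[j])
    out["total"] = truncate_pct(wrong / total)
    return out


# ---------------------------------------------------------------------------
# Detection matching
# ---------------------------------------------------------------------------


@dataclass
class MatchedPair:
    pred: BBox
    gt: BBox
    iou: float


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    unmatched_predictions: list[BBox]
    unmatched_ground_truth: list[BBox]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_predictions)

    @property
    def fn(self) -> int:
        return len(self.unmatched_ground_truth)

    def metrics(self) -> ClassMetrics:
        return precision_recall_f1(self.tp, self.fp, self.fn)


def _as_boxes_scores(predictions) -> tuple[list[BBox], list[float]]:
    boxes: list[BBox] = []
    scores: list[float] = []
    for p in predictions:
        if hasattr(p, "box"):
            boxes.append(p.box)
            scores.append(float(p.score))
        else:
            boxes.append(p)
            scores.append(float(p.score) if p.score is not None else 1.0)
    return boxes, scores


def match_detections(
    predictions,
    ground_truth: Sequence[BBox],
    iou_threshold: float = 0.5,
    method: str = "greedy",
) -> MatchResult:
    """Match predicted boxes to ground truth at an IoU threshold.

    ``greedy`` (the default, standard detection practice) walks predictions
    in descending score order; each takes the highest-IoU still-unmatched
    ground-truth box with IoU at or above the threshold.  ``optimal``
    maximizes the number of matched pairs via the assignment problem.
    Every box appears in at most one pair.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in (0, 1]")
    if method not in ("greedy", "optimal"):
        raise ValueError("method must be 'greedy' or 'optimal'")
    pred_boxes, scores = _as_boxes_scores(predictions)
    gt_boxes = list(ground_truth)

    if not pred_boxes or not gt_boxes:
        return MatchResult(pairs=[], unmatched_predictions=pred_boxes, unmatched_ground_truth=gt_boxes)

    iou = np.array([[box_iou(p, g) for g in gt_boxes] for p in pred_boxes])

    pairs: list[MatchedPair] = []
    matched_pred: set[int] = set()
    matched_gt: set[int] = set()

    if method == "greedy":
        order = sorted(range(len(pred_boxes)), key=lambda i: (-scores[i], i))
        for i in order:
            feasible = [(iou[i, j], -j) for j in range(len(gt_boxes)) if j not in matched_gt and iou[i, j] >= iou_threshold]
            if not feasible:
                continue
            best_iou, neg_j = max(feasible)
            j = -neg_j
            pairs.append(MatchedPair(pred=pred_boxes[i], gt=gt_boxes[j], iou=float(best_iou)))
            matched_pred.add(i)
            matched_gt.add(j)
    else:
        # maximize match count, then total IoU, via the assignment problem
        feasible = iou >= iou_threshold
        cost = -(feasible.astype(float) * (1.0 + iou))
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if feasible[i, j]:
                pairs.append(MatchedPair(pred=pred_boxes[i], gt=gt_boxes[j], iou=float(iou[i, j])))
                matched_pred.add(i)
                matched_gt.add(j)

    return MatchResult(
        pairs=pairs,
        unmatched_predictions=[pred_boxes[i] for i in range(len(pred_boxes)) if i not in matched_pred],
        unmatched_ground_truth=[gt_boxes[j] for j in range(len(gt_boxes)) if j not in matched_gt],
    )


# ---------------------------------------------------------------------------
# Posture-stratified detectability
# ---------------------------------------------------------------------------


def posture_detectability(records) -> pd.DataFrame:
    """Per-posture detected/missed counts and rates, sorted by detectability.

    ``records`` is either an iterable of ``(posture, detected)`` pairs or a
    mapping ``posture -> {"detected": n, "missed": m}`` (the survey report's
    ``per_posture`` field).  Records without a posture tag are excluded with
    a warning.
    """
    tallies: dict[str, dict[str, int]] = {}
    n_untagged = 0
    if hasattr(records, "items"):
        for posture, entry in records.items():
            if posture in (None, "untagged"):
                n_untagged += entry.get("detected", 0) + entry.get("missed", 0)
                continue
            tallies[posture] = {"detected": int(entry["detected"]), "missed": int(entry["missed"])}
    else:
        for posture, detected in records:
            if posture is None:
                n_untagged += 1
                continue
            entry = tallies.setdefault(posture, {"detected": 0, "missed": 0})
            entry["detected" if detected else "missed"] += 1
    if n_untagged:
        logger.warning("%d whale record(s) without a posture tag were excluded", n_untagged)
    rows = []
    for posture, entry in tallies.items():
        n = entry["detected"] + entry["missed"]
        rows.append(
            {
                "posture": posture,
                "detected": entry["detected"],
                "missed": entry["missed"],
                "detection_rate_pct": truncate_pct(entry["detected"] / n) if n else 0.0,
            }
        )
    frame = pd.DataFrame(rows, columns=["posture", "detected", "missed", "detection_rate_pct"])
    return frame.sort_values("detection_rate_pct", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass
class KFoldResult:
    per_fold: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_of: list[int]  # fold index of every dataset item


def _stratified_folds(labels: Sequence[str], k: int, rng: np.random.Generator) -> list[int]:
    """Assign each item a fold, stratified by label when possible."""
    labels = list(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    stratified = all(c >= k for c in counts.values())
    if not stratified:
        logger.warning("a class has fewer than k members; falling back to non-stratified folds")
    fold_of = [0] * len(labels)
    if stratified:
        for lab in counts:
            idx = [i for i, l in enumerate(labels) if l == lab]
            perm = rng.permutation(len(idx))
            for pos, p in enumerate(perm):
                fold_of[idx[int(p)]] = pos % k
    else:
        perm = rng.permutation(len(labels))
        for pos, p in enumerate(perm):
            fold_of[int(p)] = pos % k
    return fold_of


def kfold_evaluate(
    dataset,
    k: int,
    pipeline_factory: Callable,
    seed: int = 0,
) -> KFoldResult:
    """Stratified k-fold evaluation.

    ``pipeline_factory(dataset, train_idx, test_idx)`` trains on the train
    indices, evaluates on the test indices and returns a dict of numeric
    metrics (at least ``"f1"``).  Folds are disjoint, exhaustive, and
    deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = list(getattr(dataset, "labels"))
    if len(labels) < k:
        raise ValueError("dataset smaller than the number of folds")
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(labels, k, rng)

    per_fold: list[dict] = []
    for fold in range(k):
        test_idx = [i for i, f in enumerate(fold_of) if f == fold]
        train_idx = [i for i, f in enumerate(fold_of) if f != fold]
        per_fold.append(dict(pipeline_factory(dataset, train_idx, test_idx)))

    keys = sorted({key for row in per_fold for key in row if isinstance(row[key], (int, float))})
    mean = {key: float(np.mean([row[key] for row in per_fold if key in row])) for key in keys}
    sd = {key: float(np.std([row[key] for row in per_fold if key in row], ddof=1)) for key in keys}
    return KFoldResult(per_fold=per_fold, mean=mean, sd=sd, fold_of=fold_of)


# ---------------------------------------------------------------------------
# Survey report evaluation and comparison
# ---------------------------------------------------------------------------


@dataclass
class EvaluatedReport:
    """Whale-level counting evaluation of one survey report."""

    mode: str
    ground_truth_id: str
    counting: ClassMetrics
    per_posture: pd.DataFrame | None = None
    stage1_confusion: ConfusionMatrix3 | None = None

    @property
    def overall_f1_pct(self) -> float:
        return self.counting.f1_pct


def evaluate_report(
    report,
    annotations,
    iou_threshold: float = 0.3,
) -> EvaluatedReport:
    """Evaluate a survey report against ground-truth scene annotations.

    Counting metrics are computed end to end at the whale level: every
    merged detection is matched to ground-truth whale boxes per scene at
    the given IoU threshold.  For cascade reports the stage-1 cell-level
    confusion matrix is also computed by assigning ground truth to the
    report's grid cells.
    """
    from .scenes import assign_ground_truth

    tp = fp = fn = 0
    posture_records: list[tuple[str | None, bool]] = []
    true_cell_labels: list[str] = []
    pred_cell_labels: list[str] = []

    for sr in report.scene_results:
        ann = annotations.get(sr.scene_id)
        if ann is None:
            raise ValueError(f"no ground truth for scene {sr.scene_id!r}")
        gt = ann.whale_boxes()
        result = match_detections(sr.detections, gt, iou_threshold=iou_threshold)
        tp += result.tp
        fp += result.fp
        fn += result.fn
        matched_gt = {id(pair.gt) for pair in result.pairs}
        for b in gt:
            posture_records.append((b.posture, id(b) in matched_gt))

        if sr.cell_results and sr.cell_results[0].predicted_class is not None:
            cells = [cr.cell for cr in sr.cell_results]
            gt_cells = assign_ground_truth(ann, cells)
            true_cell_labels.extend(ca.class_label for ca in gt_cells)
            pred_cell_labels.extend(cr.predicted_class for cr in sr.cell_results)

    confusion = None
    if true_cell_labels:
        confusion = ConfusionMatrix3.from_labels(true_cell_labels, pred_cell_labels)

    gt_id = "|".join(sorted(sr.scene_id for sr in report.scene_results))
    return EvaluatedReport(
        mode=report.mode,
        ground_truth_id=gt_id,
        counting=precision_recall_f1(tp, fp, fn),
        per_posture=posture_detectability(posture_records) if posture_records else None,
        stage1_confusion=confusion,
    )


@dataclass
class ComparisonSummary:
    """Two-step minus baseline, in F1 percentage points."""

    two_step_f1_pct: float
    baseline_f1_pct: float
    improvement_points: float
    two_step_fp: int | None = None
    baseline_fp: int | None = None


def compare_reports(two_step: EvaluatedReport, baseline: EvaluatedReport) -> ComparisonSummary:
    """F1 improvement (percentage points) of the two-step survey over the
    detector-alone baseline, evaluated on identical ground truth."""
    if two_step.ground_truth_id != baseline.ground_truth_id:
        raise ValueError("reports were evaluated on different ground truth; refusing to compare")
    return ComparisonSummary(
        two_step_f1_pct=two_step.overall_f1_pct,
        baseline_f1_pct=baseline.overall_f1_pct,
        improvement_points=two_step.overall_f1_pct - baseline.overall_f1_pct,
        two_step_fp=two_step.counting.false_positives,
        baseline_fp=baseline.counting.false_positives,
    )


def f1_improvement_points(two_step_f1_pct: float, baseline_f1_pct: float) -> float:
    """Percentage-point F1 difference (two-step minus baseline)."""
    return two_step_f1_pct - baseline_f1_pct
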