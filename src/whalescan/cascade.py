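"""Two-step survey orchestration: tile, filter, detect, count.

The survey walks each scene's grid in row-major order.  Stage 1 classifies
every cell; only cells judged to contain whales ("passed" cells) are handed
to the much more expensive stage-2 detector.  Detections are mapped back to
scene coordinates, duplicates of the same whale across adjacent cells are
merged, and the per-cell and total whale counts are reported.  The
detector-alone baseline runs the same machinery with the stage-1 filter
disabled, so the two modes are directly comparable.

Results are independent of scan order: cross-cell merging operates globally
in scene coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .models import ClassProbabilities, Detection, PresenceClassifier, WhaleDetector, nms
from .scenes import (
    CLASS_WHALE,
    BBox,
    GridCell,
    Scene,
    SceneAnnotation,
    box_iou,
    extract_cell_image,
    tile_scene,
)

logger = logging.getLogger("whalescan")


@dataclass
class CascadeConfig:
    """Survey configuration.

    ``presence_rule`` decides which cells pass stage 1: ``"threshold"``
    passes cells with whale probability at least ``presence_threshold``;
    ``"argmax"`` passes cells whose most probable class is whale.
    ``cross_cell_merge_iou`` governs the global NMS that removes duplicate
    detections of one whale seen from adjacent cells; boxes that merely
    touch across a cell border (within ``merge_touch_px``) are unioned
    first, since two halves of a split whale do not overlap at all.
    """

    cell_size_m: float = 71.0
    stride_m: float | None = None
    pad_policy: str = "pad-reflect"
    presence_threshold: float = 0.5
    presence_rule: str = "threshold"  # "threshold" | "argmax"
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    cross_cell_merge_iou: float = 0.5
    merge_touch_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "score_threshold", "nms_iou", "cross_cell_merge_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be > 0")
        if self.presence_rule not in ("threshold", "argmax"):
            raise ValueError("presence_rule must be 'threshold' or 'argmax'")

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class CellResult:
    """Outcome of the cascade for one grid cell."""

    cell: GridCell
    stage1: ClassProbabilities | None
    predicted_class: str | None
    passed: bool
    detections: list[Detection] = field(default_factory=list)

    @property
    def whale_count(self) -> int:
        return len(self.detections)

    def __post_init__(self) -> None:
        if not self.passed and self.detections:
            raise ValueError("a cell that did not pass stage 1 cannot hold detections")


@dataclass
class SceneResult:
    """Per-scene survey outcome: cells, merged detections."""

    scene_id: str
    pixel_size: float
    origin: tuple[float, float] | None
    cell_results: list[CellResult]
    detections: list[Detection]  # merged, scene pixel coordinates

    @property
    def whale_count(self) -> int:
        return len(self.detections)


@dataclass
class SiteSummary:
    """One row of a multi-site summary table.

    ``cells_with_whales_photo`` is the photo-interpreted (ground truth)
    whale-cell count; ``None`` marks sites where annotation was uncertain.
    """

    site_id: str
    cells_with_whales_photo: int | None
    cells_with_whales_model: int
    total_cells: int


@dataclass
class SurveyReport:
    """Aggregate survey outcome across the scenes of one run."""

    site_id: str
    mode: str  # "cascade" | "baseline"
    scene_results: list[SceneResult]
    total_cells: int
    cells_with_whales_predicted: int
    total_whale_count: int
    detector_invocations: int
    per_posture: dict[str, dict[str, int]] | None
    timings: dict[str, float]
    provenance: dict

    def site_summary(self, cells_with_whales_photo: int | None = None) -> SiteSummary:
        return SiteSummary(
            site_id=self.site_id,
            cells_with_whales_photo=cells_with_whales_photo,
            cells_with_whales_model=self.cells_with_whales_predicted,
            total_cells=self.total_cells,
        )

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "mode": self.mode,
            "total_cells": self.total_cells,
            "cells_with_whales_predicted": self.cells_with_whales_predicted,
            "total_whale_count": self.total_whale_count,
            "detector_invocations": self.detector_invocations,
            "per_posture": self.per_posture,
            "timings": self.timings,
            "provenance": self.provenance,
            "scenes": [
                {
                    "scene_id": sr.scene_id,
                    "whale_count": sr.whale_count,
                    "detections": [
                        {
                            "x_min": d.box.x_min,
                            "y_min": d.box.y_min,
                            "x_max": d.box.x_max,
                            "y_max": d.box.y_max,
                            "score": d.score,
                        }
                        for d in sr.detections
                    ],
                    "cells": [
                        {
                            "row": cr.cell.row,
                            "col": cr.cell.col,
                            "predicted_class": cr.predicted_class,
                            "p_whale": cr.stage1.p_whale if cr.stage1 else None,
                            "passed": cr.passed,
                            "whale_count": cr.whale_count,
                        }
                        for cr in sr.cell_results
                    ],
                }
                for sr in self.scene_results
            ],
        }


def _cell_passes(probs: ClassProbabilities, config: CascadeConfig) -> bool:
    if config.presence_rule == "argmax":
        return probs.predicted_class == CLASS_WHALE
    return probs.p_whale >= config.presence_threshold


def merge_cross_cell(
    detections: list[tuple[Detection, int]],
    iou_threshold: float,
    touch_px: int,
) -> list[tuple[Detection, int]]:
    """Merge duplicate detections of one whale seen from adjacent cells.

    First, boxes that overlap or touch within ``touch_px`` pixels are
    unioned (two halves of a whale split by a cell border are disjoint, so
    plain NMS cannot join them); the union keeps the top contributing
    score and the source cell of its highest-scoring member.  A global NMS
    at ``iou_threshold`` then removes residual overlapping duplicates.
    Returns (detection, source_cell_index) pairs.
    """
    if not detections:
        return []
    n = len(detections)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    boxes = [d.box for d, _ in detections]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = boxes[i], boxes[j]
            touch = (
                a.x_min - touch_px < b.x_max
                and b.x_min - touch_px < a.x_max
                and a.y_min - touch_px < b.y_max
                and b.y_min - touch_px < a.y_max
            )
            if touch:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[tuple[Detection, int]] = []
    for members in groups.values():
        best = max(members, key=lambda i: detections[i][0].score)
        det_best, cell_best = detections[best]
        x0 = min(boxes[i].x_min for i in members)
        y0 = min(boxes[i].y_min for i in members)
        x1 = max(boxes[i].x_max for i in members)
        y1 = max(boxes[i].y_max for i in members)
        box = replace(det_best.box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)
        merged.append((Detection(box=box, score=det_best.score), cell_best))

    # residual global NMS in scene coordinates
    order = sorted(range(len(merged)), key=lambda i: (-merged[i][0].score, i))
    kept: list[tuple[Detection, int]] = []
    for i in order:
        cand = merged[i]
        if all(box_iou(cand[0].box, k[0].box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def _survey(
    scenes: Sequence[Scene],
    classifier: PresenceClassifier | None,
    detector: WhaleDetector,
    config: CascadeConfig,
    mode: str,
    annotations: dict[str, SceneAnnotation] | None = None,
    site_id: str | None = None,
) -> SurveyReport:
    t_stage1 = 0.0
    t_stage2 = 0.0
    scene_results: list[SceneResult] = []
    total_cells = 0
    cells_whale_pred = 0
    invocations = 0

    for scene in scenes:
        cells = tile_scene(scene, config.cell_size_m, config.stride_m, config.pad_policy)
        total_cells += len(cells)
        raw: list[tuple[Detection, int]] = []  # (scene-coords detection, cell idx)
        cell_records: list[tuple[GridCell, ClassProbabilities | None, str | None, bool]] = []

        for idx, cell in enumerate(cells):
            patch = extract_cell_image(scene, cell)
            probs: ClassProbabilities | None = None
            predicted: str | None = None
            if mode == "cascade":
                t0 = time.perf_counter()
                probs = classifier.classify(patch)
                t_stage1 += time.perf_counter() - t0
                predicted = probs.predicted_class
                passed = _cell_passes(probs, config)
            else:
                passed = True
            cell_records.append((cell, probs, predicted, passed))
            if predicted == CLASS_WHALE:
                cells_whale_pred += 1
            if not passed:
                continue
            t0 = time.perf_counter()
            dets = detector.detect(patch, config.score_threshold, config.nms_iou)
            t_stage2 += time.perf_counter() - t0
            invocations += 1
            for d in dets:
                box = d.box.shifted(cell.x0, cell.y0)
                # clip padded-cell detections to the scene frame
                x0 = max(0.0, box.x_min)
                y0 = max(0.0, box.y_min)
                x1 = min(float(scene.width), box.x_max)
                y1 = min(float(scene.height), box.y_max)
                if x1 <= x0 or y1 <= y0:
                    continue
                box = replace(box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)
                raw.append((Detection(box=box, score=d.score), idx))

        merged = merge_cross_cell(raw, config.cross_cell_merge_iou, config.merge_touch_px)

        per_cell_dets: dict[int, list[Detection]] = {}
        for det, cell_idx in merged:
            per_cell_dets.setdefault(cell_idx, []).append(det)

        cell_results = [
            CellResult(
                cell=cell,
                stage1=probs,
                predicted_class=predicted,
                passed=passed,
                detections=per_cell_dets.get(i, []),
            )
            for i, (cell, probs, predicted, passed) in enumerate(cell_records)
        ]
        scene_results.append(
            SceneResult(
                scene_id=scene.site_id,
                pixel_size=scene.pixel_size,
                origin=scene.origin,
                cell_results=cell_results,
                detections=[d for d, _ in merged],
            )
        )

    if mode == "baseline":
        cells_whale_pred = sum(
            1 for sr in scene_results for cr in sr.cell_results if cr.whale_count > 0
        )

    per_posture = None
    if annotations is not None:
        per_posture = _posture_tallies(scene_results, annotations)

    report = SurveyReport(
        site_id=site_id or (scenes[0].site_id if len(scenes) == 1 else "survey"),
        mode=mode,
        scene_results=scene_results,
        total_cells=total_cells,
        cells_with_whales_predicted=cells_whale_pred,
        total_whale_count=sum(sr.whale_count for sr in scene_results),
        detector_invocations=invocations,
        per_posture=per_posture,
        timings={"stage1_s": t_stage1, "stage2_s": t_stage2},
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "classifier": getattr(getattr(classifier, "backbone", None), "name", None),
            "detector": getattr(getattr(detector, "backbone", None), "name", None),
        },
    )
    return report


def _posture_tallies(
    scene_results: list[SceneResult],
    annotations: dict[str, SceneAnnotation],
    iou_threshold: float = 0.3,
) -> dict[str, dict[str, int]]:
    """Per-posture detected/missed tallies of ground-truth whales."""
    from .metrics import match_detections  # local import to avoid a cycle

    tallies: dict[str, dict[str, int]] = {}
    for sr in scene_results:
        ann = annotations.get(sr.scene_id)
        if ann is None:
            continue
        gt = ann.whale_boxes()
        result = match_detections(sr.detections, gt, iou_threshold=iou_threshold)
        matched_gt = {id(pair.gt) for pair in result.pairs}
        for b in gt:
            tag = b.posture or "untagged"
            entry = tallies.setdefault(tag, {"detected": 0, "missed": 0})
            if id(b) in matched_gt:
                entry["detected"] += 1
            else:
                entry["missed"] += 1
    return tallies


def run_cascade(
    scenes: Sequence[Scene],
    classifier: PresenceClassifier,
    detector: WhaleDetector,
    config: CascadeConfig | None = None,
    annotations: dict[str, SceneAnnotation] | None = None,
    site_id: str | None = None,
) -> SurveyReport:
    """Run the full two-step survey over a set of scenes.

    The detector runs only on cells that pass the stage-1 presence rule;
    the number of detector invocations is recorded and is at most the
    number of cells.  Deterministic given models and config.
    """
    config = config or CascadeConfig()
    if scenes:
        for scene in scenes:
            if not scene.pixel_size > 0:
                raise ValueError("scene is missing a valid pixel size")
    return _survey(scenes, classifier, detector, config, "cascade", annotations, site_id)


def run_baseline(
    scenes: Sequence[Scene],
    detector: WhaleDetector,
    config: CascadeConfig | None = None,
    annotations: dict[str, SceneAnnotation] | None = None,
    site_id: str | None = None,
) -> SurveyReport:
    """Run the detector-alone baseline: every cell is analyzed, no filter."""
    config = config or CascadeConfig()
    return _survey(scenes, None, detector, config, "baseline", annotations, site_id)


@dataclass
class MultiSiteSummary:
    """Totals over per-site summary rows."""

    rows: list[SiteSummary]
    total_cells: int
    total_whale_cells_photo: int
    total_whale_cells_model: int
    n_sites_uncertain: int

    def to_dict(self) -> dict:
        return {
            "rows": [asdict(r) for r in self.rows],
            "total_cells": self.total_cells,
            "total_whale_cells_photo": self.total_whale_cells_photo,
            "total_whale_cells_model": self.total_whale_cells_model,
            "n_sites_uncertain": self.n_sites_uncertain,
        }


def aggregate_sites(
    items: Sequence[SiteSummary | SurveyReport],
    force: bool = False,
) -> MultiSiteSummary:
    """Sum per-site survey summaries into a multi-site total.

    Accepts either :class:`SiteSummary` rows (e.g. a printed survey table)
    or :class:`SurveyReport` objects; reports must share a config hash
    unless ``force`` is set.  Sites with uncertain photo-interpretation
    (``cells_with_whales_photo is None``) are excluded from the photo total
    and counted in ``n_sites_uncertain``.
    """
    rows: list[SiteSummary] = []
    hashes = set()
    for item in items:
        if isinstance(item, SurveyReport):
            hashes.add(item.provenance.get("config_hash"))
            rows.append(item.site_summary())
        else:
            rows.append(item)
    if len(hashes) > 1 and not force:
        raise ValueError("reports were produced under different configs; pass force=True to combine")
    return MultiSiteSummary(
        rows=rows,
        total_cells=sum(r.total_cells for r in rows),
        total_whale_cells_photo=sum(
            r.cells_with_whales_photo for r in rows if r.cells_with_whales_photo is not None
        ),
        total_whale_cells_model=sum(r.cells_with_whales_model for r in rows),
        n_sites_uncertain=sum(1 for r in rows if r.cells_with_whales_photo is None),
    )
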