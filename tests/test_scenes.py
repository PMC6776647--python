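"""Grid tiling, box geometry, ground-truth assignment and file formats."""

from __future__ import annotations

import numpy as np
import pytest

from whalescan import (
    BBox,
    CellAnnotation,
    Scene,
    SceneAnnotation,
    assign_ground_truth,
    box_iou,
    extract_cell_image,
    read_boxes_csv,
    read_cells_csv,
    read_coco,
    read_scene,
    tile_scene,
    write_boxes_csv,
    write_cells_csv,
    write_coco,
    write_scene,
)


def _scene(h=284, w=284, pixel_size=1.0, origin=None, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
    return Scene(image=img, pixel_size=pixel_size, origin=origin)


# ---------------------------------------------------------------------------
# BBox / IoU
# ---------------------------------------------------------------------------


def test_bbox_rejects_empty_boxes():
    with pytest.raises(ValueError):
        BBox(10, 10, 10, 20)
    with pytest.raises(ValueError):
        BBox(10, 10, 20, 5)


def test_bbox_rejects_out_of_range_score():
    with pytest.raises(ValueError):
        BBox(0, 0, 1, 1, score=1.5)


def test_box_iou_identity_and_disjoint():
    a = BBox(0, 0, 10, 10)
    assert box_iou(a, a) == 1.0
    assert box_iou(a, BBox(20, 20, 30, 30)) == 0.0


def test_box_iou_half_overlap():
    a = BBox(0, 0, 10, 10)
    b = BBox(5, 0, 15, 10)
    # intersection 50, union 150
    assert box_iou(a, b) == pytest.approx(1.0 / 3.0)


def test_box_iou_symmetric_and_bounded():
    rng = np.random.default_rng(42)
    for _ in range(200):
        x0, y0 = rng.uniform(0, 50, 2)
        a = BBox(x0, y0, x0 + rng.uniform(1, 30), y0 + rng.uniform(1, 30))
        x0, y0 = rng.uniform(0, 50, 2)
        b = BBox(x0, y0, x0 + rng.uniform(1, 30), y0 + rng.uniform(1, 30))
        iou = box_iou(a, b)
        assert 0.0 <= iou <= 1.0
        assert iou == pytest.approx(box_iou(b, a))


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def test_tile_exact_grid_284m():
    cells = tile_scene(_scene(284, 284, 1.0), cell_size_m=71.0)
    assert len(cells) == 16
    assert not any(c.padded for c in cells)


def test_tile_partition_properties_many_configs():
    rng = np.random.default_rng(7)
    n_checked = 0
    for _ in range(100):
        h = int(rng.integers(40, 400))
        w = int(rng.integers(40, 400))
        ps = float(rng.choice([0.5, 1.0, 2.0]))
        cell_m = float(rng.choice([35.5, 71.0, 50.0]))
        scene = _scene(h, w, ps)
        cell_px = int(round(cell_m / ps))
        if cell_px < 1:
            continue
        cells = tile_scene(scene, cell_size_m=cell_m)
        import math

        assert len(cells) == math.ceil(w / cell_px) * math.ceil(h / cell_px)
        # non-overlapping cover of the image
        covered = np.zeros((h, w), dtype=int)
        for c in cells:
            covered[c.y0 : min(c.y1, h), c.x0 : min(c.x1, w)] += 1
        assert (covered == 1).all()
        # padded flag exactly for cells extending past the image
        for c in cells:
            assert c.padded == (c.x1 > w or c.y1 > h)
        n_checked += 1
    assert n_checked >= 100


def test_tile_drop_policy_skips_partial_cells():
    scene = _scene(100, 100, 1.0)
    dropped = tile_scene(scene, cell_size_m=71.0, pad_policy="drop")
    assert len(dropped) == 1
    assert dropped[0].x1 <= 100 and dropped[0].y1 <= 100


def test_tile_rejects_bad_inputs():
    with pytest.raises(ValueError):
        tile_scene(_scene(), cell_size_m=0.0)
    with pytest.raises(ValueError):
        tile_scene(_scene(), cell_size_m=71.0, pad_policy="bogus")


def test_extract_cell_image_shapes_and_padding():
    scene = _scene(100, 100, 1.0)
    for policy in ("pad-reflect", "pad-zero"):
        cells = tile_scene(scene, cell_size_m=71.0, pad_policy=policy)
        for c in cells:
            img = extract_cell_image(scene, c)
            assert img.shape == (71, 71, 3)
    # interior pixels must be identical to the source
    c0 = tile_scene(scene, cell_size_m=71.0)[0]
    img = extract_cell_image(scene, c0)
    assert (img[:71, :71] == scene.image[:71, :71]).all()


def test_extract_cell_pad_zero_fills_zero():
    scene = _scene(80, 80, 1.0)
    cells = tile_scene(scene, cell_size_m=71.0, pad_policy="pad-zero")
    padded = [c for c in cells if c.padded]
    assert padded
    img = extract_cell_image(scene, padded[-1])
    assert (img[-1, -1] == 0).all()


# ---------------------------------------------------------------------------
# Ground-truth assignment
# ---------------------------------------------------------------------------


def test_assign_center_rule_counts_straddling_whale_once():
    scene = _scene(142, 142, 1.0)
    cells = tile_scene(scene, cell_size_m=71.0)
    # whale straddling the vertical cell border, center in the left cell
    ann = SceneAnnotation(
        scene_ref="s", boxes=[BBox(60, 10, 80, 20, class_label="whale", posture="logging")]
    )
    cas = assign_ground_truth(ann, cells)
    assert sum(ca.whale_count for ca in cas) == 1
    assert cas[0].class_label == "whale"  # center x=70 < 71: left cell
    assert cas[1].class_label == "water_rock"


def test_assign_label_priority_whale_over_ship():
    scene = _scene(71, 71, 1.0)
    cells = tile_scene(scene, cell_size_m=71.0)
    ann = SceneAnnotation(
        scene_ref="s",
        boxes=[
            BBox(5, 5, 15, 15, class_label="ship"),
            BBox(30, 30, 40, 40, class_label="whale", posture="logging"),
        ],
    )
    cas = assign_ground_truth(ann, cells)
    assert cas[0].class_label == "whale"
    assert cas[0].whale_count == 1
    assert cas[0].posture == "logging"


def test_assign_count_conservation_random_configs():
    rng = np.random.default_rng(11)
    for _ in range(100):
        h = int(rng.integers(71, 400))
        w = int(rng.integers(71, 400))
        scene = _scene(h, w, 1.0, seed=int(rng.integers(1 << 30)))
        cells = tile_scene(scene, cell_size_m=71.0)
        boxes = []
        n = int(rng.integers(0, 12))
        for _ in range(n):
            x0 = float(rng.uniform(0, w - 2))
            y0 = float(rng.uniform(0, h - 2))
            boxes.append(
                BBox(
                    x0,
                    y0,
                    x0 + float(rng.uniform(1, 20)),
                    y0 + float(rng.uniform(1, 20)),
                    class_label="whale",
                    posture="logging",
                )
            )
        ann = SceneAnnotation(scene_ref="s", boxes=boxes)
        cas = assign_ground_truth(ann, cells)
        # every whale whose center falls inside the (padded) grid lands in
        # exactly one cell -- a straddling whale is never double counted
        gx = max(c.x1 for c in cells)
        gy = max(c.y1 for c in cells)
        inside = sum(
            1
            for b in boxes
            if 0 <= (b.x_min + b.x_max) / 2 < gx and 0 <= (b.y_min + b.y_max) / 2 < gy
        )
        assert sum(ca.whale_count for ca in cas) == inside


def test_cell_annotation_invariants():
    from whalescan import GridCell

    cell = GridCell(0, 0, 0, 0, 71, 71, 71.0)
    with pytest.raises(ValueError):
        CellAnnotation(cell=cell, class_label="whale", whale_boxes=[])
    with pytest.raises(ValueError):
        CellAnnotation(cell=cell, class_label="water_rock", posture="logging")
    with pytest.raises(ValueError):
        CellAnnotation(cell=cell, class_label="seagull")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def test_scene_round_trip(tmp_path):
    scene = _scene(64, 48, 0.5, origin=(12.5, -3.25))
    path = tmp_path / "s.png"
    write_scene(scene, path)
    back = read_scene(path)
    assert (back.image == scene.image).all()
    assert back.pixel_size == scene.pixel_size
    assert back.origin == scene.origin


def test_read_scene_requires_pixel_size_without_sidecar(tmp_path):
    import imageio.v3 as iio

    path = tmp_path / "bare.png"
    iio.imwrite(path, np.zeros((8, 8, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        read_scene(path)
    scene = read_scene(path, pixel_size=2.0)
    assert scene.pixel_size == 2.0


def _sample_annotations():
    return [
        SceneAnnotation(
            scene_ref="scene_a",
            boxes=[
                BBox(1.0, 2.0, 11.0, 8.0, class_label="whale", posture="logging"),
                BBox(30.0, 40.0, 55.5, 44.25, class_label="ship"),
            ],
        ),
        SceneAnnotation(scene_ref="scene_b", boxes=[]),
    ]


def test_coco_round_trip(tmp_path):
    anns = _sample_annotations()
    path = tmp_path / "ann.json"
    write_coco(anns, path)
    back = read_coco(path)
    assert [a.scene_ref for a in back] == ["scene_a", "scene_b"]
    b = back[0].boxes[0]
    assert (b.x_min, b.y_min, b.x_max, b.y_max) == (1.0, 2.0, 11.0, 8.0)
    assert b.class_label == "whale" and b.posture == "logging"
    assert back[0].boxes[1].class_label == "ship"
    assert back[1].boxes == []


def test_boxes_csv_round_trip(tmp_path):
    anns = _sample_annotations()
    path = tmp_path / "boxes.csv"
    write_boxes_csv(anns, path)
    back = read_boxes_csv(path)
    # empty scenes carry no rows, so only scene_a comes back
    assert len(back) == 1 and back[0].scene_ref == "scene_a"
    got = back[0].boxes[0]
    assert (got.x_min, got.y_min, got.x_max, got.y_max) == (1.0, 2.0, 11.0, 8.0)
    assert got.posture == "logging"


def test_cells_csv_round_trip(tmp_path):
    scene = _scene(142, 71, 1.0)
    cells = tile_scene(scene, cell_size_m=71.0)
    ann = SceneAnnotation(
        scene_ref="s", boxes=[BBox(5, 5, 15, 15, class_label="whale", posture="blowing")]
    )
    cas = assign_ground_truth(ann, cells)
    path = tmp_path / "cells.csv"
    write_cells_csv(cas, path, site_id="siteX")
    back = read_cells_csv(path)
    assert len(back) == len(cas)
    assert back[0].class_label == "whale"
    assert back[0].whale_count == 1
    assert back[0].posture == "blowing"
    got = back[0].whale_boxes[0]
    # boxes are stored cell-local
    assert (got.x_min, got.y_min, got.x_max, got.y_max) == (5.0, 5.0, 15.0, 15.0)
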