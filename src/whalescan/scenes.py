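"""Domain types and tiling for very-high-resolution ocean survey scenes.

A survey scene is a large RGB raster with a known ground sampling distance
(meters per pixel).  For whale surveys the scene is cut into a regular grid of
square cells (default 71 x 71 m, roughly twice the length of the largest
whales) and every cell is treated as an independent classification /
detection unit.

Coordinate convention (used throughout the package): pixel coordinates with
the origin at the top-left corner, x increasing rightward (columns), y
increasing downward (rows).  All boxes and cell bounds are half-open
intervals ``[x0, x1) x [y0, y1)``.  Metric bounds are derived as
``pixel * pixel_size``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("whalescan")

# Class taxonomy of the stage-1 presence filter.
CLASS_WHALE = "whale"
CLASS_SHIP = "ship"
CLASS_WATER_ROCK = "water_rock"
CLASS_ORDER: tuple[str, ...] = (CLASS_WHALE, CLASS_SHIP, CLASS_WATER_ROCK)

# Surfacing behaviours that modulate how visible a whale is from above.
POSTURES: tuple[str, ...] = (
    "logging",
    "breaching",
    "spyhopping",
    "blowing",
    "peduncle",
    "submerged",
)

PAD_POLICIES = ("pad-reflect", "pad-zero", "drop")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """An RGB survey raster with its ground sampling distance.

    Parameters
    ----------
    image:
        ``(height, width, 3)`` uint8 array.
    pixel_size:
        Meters per pixel, strictly positive.
    origin:
        Optional planar/geodetic coordinate of the top-left pixel corner,
        as an ``(x, y)`` pair.  Purely carried through to outputs.
    site_id:
        Free-text identifier of the survey site.
    """

    image: np.ndarray
    pixel_size: float
    origin: tuple[float, float] | None = None
    site_id: str = "scene"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("scene image must be height x width x 3 (RGB)")
        if self.image.shape[0] < 1 or self.image.shape[1] < 1:
            raise ValueError("scene image must be at least 1 x 1 pixels")
        if self.image.dtype != np.uint8:
            raise ValueError("scene image must be 8-bit per channel (uint8)")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def height(self) -> int:
        return int(self.image.shape[0])

    @property
    def width(self) -> int:
        return int(self.image.shape[1])

    @property
    def width_m(self) -> float:
        return self.width * self.pixel_size

    @property
    def height_m(self) -> float:
        return self.height * self.pixel_size


@dataclass(frozen=True)
class GridCell:
    """One square tile of a scene's survey grid.

    ``pixel_bounds`` is the half-open rectangle ``(x0, y0, x1, y1)`` in
    parent-scene pixel coordinates.  ``padded`` marks cells whose nominal
    extent runs past the scene edge; how the missing pixels are filled is
    recorded in ``pad_policy``.
    """

    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    size_m: float
    padded: bool = False
    pad_policy: str = "pad-reflect"

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("grid indices must be non-negative")
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("cell pixel bounds must be non-empty")

    @property
    def width_px(self) -> int:
        return self.x1 - self.x0

    @property
    def height_px(self) -> int:
        return self.y1 - self.y0

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class BBox:
    """Axis-aligned box, half-open pixel coordinates, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_label: str = CLASS_WHALE
    score: float | None = None
    posture: str | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("box must have positive width and height")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.posture is not None and self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def shifted(self, dx: float, dy: float) -> "BBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def box_iou(a: BBox | Sequence[float], b: BBox | Sequence[float]) -> float:
    """Intersection-over-union of two half-open boxes."""
    ax0, ay0, ax1, ay1 = a.as_tuple() if isinstance(a, BBox) else a
    bx0, by0, bx1, by1 = b.as_tuple() if isinstance(b, BBox) else b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


@dataclass
class CellAnnotation:
    """Ground truth for one grid cell.

    Invariants: ``whale_count == len(whale_boxes)``; the label is ``whale``
    exactly when at least one whale box was assigned; a posture tag is
    present only for whale cells.
    """

    cell: GridCell
    class_label: str
    whale_boxes: list[BBox] = field(default_factory=list)
    posture: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if (self.class_label == CLASS_WHALE) != (len(self.whale_boxes) >= 1):
            raise ValueError("label is 'whale' iff the cell holds >= 1 whale box")
        if self.posture is not None and self.class_label != CLASS_WHALE:
            raise ValueError("posture tags are only valid on whale cells")

    @property
    def whale_count(self) -> int:
        return len(self.whale_boxes)


@dataclass
class SceneAnnotation:
    """Ground-truth boxes for a whole scene, in scene pixel coordinates."""

    scene_ref: str
    boxes: list[BBox] = field(default_factory=list)

    def whale_boxes(self) -> list[BBox]:
        return [b for b in self.boxes if b.class_label == CLASS_WHALE]


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def tile_scene(
    scene: Scene,
    cell_size_m: float = 71.0,
    stride_m: float | None = None,
    pad_policy: str = "pad-reflect",
) -> list[GridCell]:
    """Cut a scene into a row-major grid of square cells.

    With ``stride_m == cell_size_m`` (the default, a non-overlapping grid)
    the produced cells partition the scene: every pixel belongs to exactly
    one cell.  Under ``pad-reflect``/``pad-zero`` the grid covers the whole
    scene and edge cells keep their nominal pixel extent, flagged
    ``padded``; under ``drop`` only cells that fit entirely inside the
    scene are returned.
    """
    if stride_m is None:
        stride_m = cell_size_m
    if not (cell_size_m > 0 and stride_m > 0):
        raise ValueError("cell_size_m and stride_m must be > 0")
    if pad_policy not in PAD_POLICIES:
        raise ValueError(f"pad_policy must be one of {PAD_POLICIES}")

    cell_px = int(round(cell_size_m / scene.pixel_size))
    stride_px = int(round(stride_m / scene.pixel_size))
    if cell_px < 1:
        raise ValueError("cell size is smaller than one pixel")
    if stride_px < 1:
        raise ValueError("stride is smaller than one pixel")

    n_rows = math.ceil(scene.height / stride_px)
    n_cols = math.ceil(scene.width / stride_px)

    cells: list[GridCell] = []
    for r in range(n_rows):
        y0 = r * stride_px
        if y0 >= scene.height:
            continue
        for c in range(n_cols):
            x0 = c * stride_px
            if x0 >= scene.width:
                continue
            x1 = x0 + cell_px
            y1 = y0 + cell_px
            padded = x1 > scene.width or y1 > scene.height
            if padded and pad_policy == "drop":
                continue
            cells.append(
                GridCell(
                    row=r,
                    col=c,
                    x0=x0,
                    y0=y0,
                    x1=x1,
                    y1=y1,
                    size_m=cell_size_m,
                    padded=padded,
                    pad_policy=pad_policy,
                )
            )
    return cells


def extract_cell_image(scene: Scene, cell: GridCell) -> np.ndarray:
    """Crop one cell out of its scene, filling out-of-scene pixels.

    Padded regions are filled according to the cell's pad policy
    (``pad-reflect`` mirrors the scene content, ``pad-zero`` fills black).
    """
    if cell.x0 >= scene.width or cell.y0 >= scene.height:
        raise ValueError("cell lies outside the scene")
    x_hi = min(cell.x1, scene.width)
    y_hi = min(cell.y1, scene.height)
    crop = scene.image[cell.y0 : y_hi, cell.x0 : x_hi]
    pad_y = cell.height_px - crop.shape[0]
    pad_x = cell.width_px - crop.shape[1]
    if pad_y == 0 and pad_x == 0:
        return crop.copy()
    if cell.pad_policy == "drop":
        raise ValueError("cell extends past the scene under pad policy 'drop'")
    mode = "reflect" if cell.pad_policy == "pad-reflect" else "constant"
    return np.pad(crop, ((0, pad_y), (0, pad_x), (0, 0)), mode=mode)


# ---------------------------------------------------------------------------
# Ground-truth assignment
# ---------------------------------------------------------------------------


def assign_ground_truth(
    annotation: SceneAnnotation,
    cells: Sequence[GridCell],
) -> list[CellAnnotation]:
    """Distribute scene-level ground-truth boxes onto grid cells.

    Each box is assigned to exactly one cell — the cell containing the box
    center — so a whale straddling a cell border is counted once.  Cell
    labels follow the priority whale > ship > water_rock.  Boxes whose
    center falls outside every cell (possible under the ``drop`` pad
    policy) are left unassigned with a logged warning.

    Whale boxes are translated into cell-local coordinates.  A whale cell's
    posture tag is the most common posture among its whales (first seen
    wins ties), mirroring annotation by dominant posture.
    """
    per_cell_whales: dict[int, list[BBox]] = {i: [] for i in range(len(cells))}
    per_cell_has_ship: dict[int, bool] = {i: False for i in range(len(cells))}
    unassigned: list[BBox] = []

    for box in annotation.boxes:
        cx, cy = box.center
        target = None
        for i, cell in enumerate(cells):
            if cell.contains_point(cx, cy):
                target = i
                break
        if target is None:
            unassigned.append(box)
            continue
        if box.class_label == CLASS_WHALE:
            cell = cells[target]
            per_cell_whales[target].append(box.shifted(-cell.x0, -cell.y0))
        elif box.class_label == CLASS_SHIP:
            per_cell_has_ship[target] = True

    if unassigned:
        logger.warning(
            "%d ground-truth box(es) fell outside every grid cell and were "
            "left unassigned",
            len(unassigned),
        )

    annotations: list[CellAnnotation] = []
    for i, cell in enumerate(cells):
        whales = per_cell_whales[i]
        if whales:
            postures = [b.posture for b in whales if b.posture is not None]
            posture = None
            if postures:
                counts: dict[str, int] = {}
                for p in postures:
                    counts[p] = counts.get(p, 0) + 1
                posture = max(counts, key=lambda p: (counts[p], -postures.index(p)))
            annotations.append(
                CellAnnotation(cell=cell, class_label=CLASS_WHALE, whale_boxes=whales, posture=posture)
            )
        elif per_cell_has_ship[i]:
            annotations.append(CellAnnotation(cell=cell, class_label=CLASS_SHIP))
        else:
            annotations.append(CellAnnotation(cell=cell, class_label=CLASS_WATER_ROCK))
    return annotations


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def read_scene(
    path: str | Path,
    pixel_size: float | None = None,
    site_id: str | None = None,
) -> Scene:
    """Read a scene raster (PNG/JPEG/TIFF).

    The pixel size comes from, in order of precedence: the ``pixel_size``
    argument, or a sidecar JSON file ``<raster>.meta.json`` with keys
    ``pixel_size`` and optionally ``origin`` and ``site_id``.
    """
    path = Path(path)
    image = np.asarray(iio.imread(path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[2] == 4:
        image = image[:, :, :3]
    origin = None
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if pixel_size is None:
        raise ValueError(
            f"no pixel size for {path.name}: pass pixel_size or provide "
            f"{sidecar.name} with a 'pixel_size' key"
        )
    if meta.get("origin") is not None:
        origin = tuple(meta["origin"])
    return Scene(
        image=image.astype(np.uint8),
        pixel_size=float(pixel_size),
        origin=origin,
        site_id=site_id or meta.get("site_id", path.stem),
    )


def write_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene raster plus its sidecar metadata JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, scene.image)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": scene.pixel_size,
                "origin": list(scene.origin) if scene.origin else None,
                "site_id": scene.site_id,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Annotation I/O: COCO-style JSON and a flat CSV dialect
# ---------------------------------------------------------------------------

COCO_CATEGORIES = [
    {"id": 1, "name": CLASS_WHALE},
    {"id": 2, "name": CLASS_SHIP},
]
_COCO_ID_BY_NAME = {c["name"]: c["id"] for c in COCO_CATEGORIES}
_COCO_NAME_BY_ID = {c["id"]: c["name"] for c in COCO_CATEGORIES}


def write_coco(
    annotations: Iterable[SceneAnnotation],
    path: str | Path,
    image_sizes: dict[str, tuple[int, int]] | None = None,
) -> None:
    """Write scene annotations as COCO-style detection JSON.

    ``image_sizes`` maps scene_ref -> (height, width); sizes default to 0
    when unknown.  Posture tags are stored under ``attributes.posture``.
    """
    images = []
    annos = []
    next_id = 1
    for img_id, ann in enumerate(annotations, start=1):
        h, w = (image_sizes or {}).get(ann.scene_ref, (0, 0))
        images.append({"id": img_id, "file_name": ann.scene_ref, "height": h, "width": w})
        for box in ann.boxes:
            entry = {
                "id": next_id,
                "image_id": img_id,
                "category_id": _COCO_ID_BY_NAME[box.class_label],
                "bbox": [box.x_min, box.y_min, box.x_max - box.x_min, box.y_max - box.y_min],
                "area": box.area,
                "iscrowd": 0,
            }
            if box.posture is not None:
                entry["attributes"] = {"posture": box.posture}
            if box.score is not None:
                entry["score"] = box.score
            annos.append(entry)
            next_id += 1
    payload = {"images": images, "annotations": annos, "categories": COCO_CATEGORIES}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_coco(path: str | Path) -> list[SceneAnnotation]:
    """Read COCO-style detection JSON back into scene annotations."""
    payload = json.loads(Path(path).read_text())
    name_by_img = {img["id"]: img["file_name"] for img in payload["images"]}
    cat_names = {c["id"]: c["name"] for c in payload.get("categories", COCO_CATEGORIES)}
    by_scene: dict[str, list[BBox]] = {name: [] for name in name_by_img.values()}
    for a in payload["annotations"]:
        x, y, w, h = a["bbox"]
        posture = (a.get("attributes") or {}).get("posture")
        by_scene[name_by_img[a["image_id"]]].append(
            BBox(
                x_min=x,
                y_min=y,
                x_max=x + w,
                y_max=y + h,
                class_label=cat_names.get(a["category_id"], _COCO_NAME_BY_ID.get(a["category_id"], CLASS_WHALE)),
                score=a.get("score"),
                posture=posture,
            )
        )
    return [SceneAnnotation(scene_ref=name, boxes=boxes) for name, boxes in by_scene.items()]


CSV_BOX_HEADER = ["scene_id", "x_min", "y_min", "x_max", "y_max", "class", "posture"]


def write_boxes_csv(annotations: Iterable[SceneAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_BOX_HEADER)
        for ann in annotations:
            for b in ann.boxes:
                writer.writerow(
                    [ann.scene_ref, b.x_min, b.y_min, b.x_max, b.y_max, b.class_label, b.posture or ""]
                )


def read_boxes_csv(path: str | Path) -> list[SceneAnnotation]:
    by_scene: dict[str, list[BBox]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            by_scene.setdefault(row["scene_id"], []).append(
                BBox(
                    x_min=float(row["x_min"]),
                    y_min=float(row["y_min"]),
                    x_max=float(row["x_max"]),
                    y_max=float(row["y_max"]),
                    class_label=row["class"],
                    posture=row["posture"] or None,
                )
            )
    return [SceneAnnotation(scene_ref=k, boxes=v) for k, v in by_scene.items()]


CSV_CELL_HEADER = [
    "site_id",
    "row",
    "col",
    "x0",
    "y0",
    "x1",
    "y1",
    "label",
    "whale_count",
    "posture",
    "boxes",
]


def write_cells_csv(
    cell_annotations: Iterable[CellAnnotation], path: str | Path, site_id: str = "scene"
) -> None:
    """Write per-cell annotations as a flat CSV table.

    Whale boxes (cell-local coordinates) are serialized in a ``boxes``
    column as ``x0:y0:x1:y1`` separated by ``;`` so that the table round
    trips losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_CELL_HEADER)
        for ca in cell_annotations:
            boxes = ";".join(
                f"{b.x_min}:{b.y_min}:{b.x_max}:{b.y_max}" for b in ca.whale_boxes
            )
            writer.writerow(
                [
                    site_id,
                    ca.cell.row,
                    ca.cell.col,
                    ca.cell.x0,
                    ca.cell.y0,
                    ca.cell.x1,
                    ca.cell.y1,
                    ca.class_label,
                    ca.whale_count,
                    ca.posture or "",
                    boxes,
                ]
            )


def read_cells_csv(path: str | Path) -> list[CellAnnotation]:
    out: list[CellAnnotation] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cell = GridCell(
                row=int(row["row"]),
                col=int(row["col"]),
                x0=int(row["x0"]),
                y0=int(row["y0"]),
                x1=int(row["x1"]),
                y1=int(row["y1"]),
                size_m=(int(row["x1"]) - int(row["x0"])),
            )
            boxes = []
            if row.get("boxes"):
                for token in row["boxes"].split(";"):
                    x0, y0, x1, y1 = (float(v) for v in token.split(":"))
                    boxes.append(BBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1))
            out.append(
                CellAnnotation(
                    cell=cell,
                    class_label=row["label"],
                    whale_boxes=boxes,
                    posture=row["posture"] or None,
                )
            )
    return out
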