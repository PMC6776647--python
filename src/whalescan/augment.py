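"""Training-time data augmentation for patches and their boxes.

The recipe: rotation by a uniformly random angle in [0, 360) degrees,
horizontal flipping of half the training images, random cropping, random
rescaling, and random per-image brightness scaling by a factor of up to 50%.
Geometric operations are applied consistently to the image and to any
bounding boxes; boxes that shrink below a minimum visible area (e.g. a whale
mostly cropped away) are dropped.

Rotation exposes no corners: the image is filled by reflection, consistent
with how edge grid cells are padded elsewhere in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

from .scenes import BBox

logger = logging.getLogger("whalescan")


@dataclass
class AugmentConfig:
    """Augmentation hyperparameters.

    ``brightness_max_factor`` f draws the per-image multiplier from
    [1 - f, 1 + f]; ``crop_min_fraction`` is the minimum retained area of a
    random crop (the crop is resized back to the input size); ``scale_range``
    bounds the isotropic rescale.  ``min_box_area_fraction`` drops boxes that
    kept less than that fraction of their original area after cropping and
    clipping.
    """

    rotation_range_deg: tuple[float, float] = (0.0, 360.0)
    flip_probability: float = 0.5
    crop_enabled: bool = True
    crop_min_fraction: float = 0.7
    scale_range: tuple[float, float] = (0.75, 1.25)
    brightness_max_factor: float = 0.5
    min_box_area_fraction: float = 0.25
    output_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not (0.0 <= lo <= hi <= 360.0):
            raise ValueError("rotation range must lie within [0, 360]")
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ValueError("flip_probability must lie in [0, 1]")
        if not (0.0 <= self.brightness_max_factor <= 1.0):
            raise ValueError("brightness_max_factor must lie in [0, 1]")
        if not (0.0 < self.crop_min_fraction <= 1.0):
            raise ValueError("crop_min_fraction must lie in (0, 1]")
        if not (0.0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale_range must be positive and ordered")


IDENTITY_CONFIG = AugmentConfig(
    rotation_range_deg=(0.0, 0.0),
    flip_probability=0.0,
    crop_enabled=False,
    scale_range=(1.0, 1.0),
    brightness_max_factor=0.0,
)


# ---------------------------------------------------------------------------
# Box geometry helpers
# ---------------------------------------------------------------------------


def rotate_box(box: BBox, angle_deg: float, height: int, width: int) -> BBox:
    """Axis-aligned hull of a box rotated about the image center.

    Positive angles rotate counter-clockwise (visually), matching
    ``skimage.transform.rotate``.  In image coordinates (y down) a visual
    counter-clockwise rotation by theta maps a point p to
    ``c + R(-theta) (p - c)`` with R the standard rotation matrix.
    """
    cy, cx = (height / 2.0, width / 2.0)
    theta = math.radians(angle_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    corners = [
        (box.x_min, box.y_min),
        (box.x_max, box.y_min),
        (box.x_min, box.y_max),
        (box.x_max, box.y_max),
    ]
    xs, ys = [], []
    for x, y in corners:
        dx, dy = x - cx, y - cy
        xs.append(cx + cos_t * dx + sin_t * dy)
        ys.append(cy - sin_t * dx + cos_t * dy)
    return replace(box, x_min=min(xs), y_min=min(ys), x_max=max(xs), y_max=max(ys))


def flip_box_horizontal(box: BBox, width: int) -> BBox:
    return replace(box, x_min=width - box.x_max, x_max=width - box.x_min)


def _scale_box(box: BBox, factor: float) -> BBox:
    return replace(
        box,
        x_min=box.x_min * factor,
        y_min=box.y_min * factor,
        x_max=box.x_max * factor,
        y_max=box.y_max * factor,
    )


def _clip_box(box: BBox, height: float, width: float) -> BBox | None:
    x0 = max(0.0, box.x_min)
    y0 = max(0.0, box.y_min)
    x1 = min(float(width), box.x_max)
    y1 = min(float(height), box.y_max)
    if x1 <= x0 or y1 <= y0:
        return None
    return replace(box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------


def augment_patch(
    image: np.ndarray,
    boxes: Sequence[BBox] | None = None,
    config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[BBox]]:
    """Apply one random draw of the augmentation recipe.

    Order of operations: rotate, flip, rescale, crop (then resize back),
    brightness.  Boxes follow every geometric operation and are clipped to
    the output; boxes retaining less than ``min_box_area_fraction`` of their
    original area are dropped with a warning.  Output dtype matches the
    input (uint8 inputs are clamped to [0, 255]).
    """
    if image is None or image.size == 0:
        raise ValueError("image must be non-empty")
    config = config or AugmentConfig()
    rng = rng or np.random.default_rng(config.seed)
    boxes_in = list(boxes) if boxes else []
    original_areas = [b.area for b in boxes_in]
    out_boxes = list(boxes_in)

    was_uint8 = image.dtype == np.uint8
    img = image.astype(np.float64) / 255.0 if was_uint8 else image.astype(np.float64)
    h, w = img.shape[:2]

    # rotation (reflection fill, no corner artifacts)
    lo, hi = config.rotation_range_deg
    angle = float(rng.uniform(lo, hi)) if hi > lo else lo
    if angle % 360.0 != 0.0:
        img = sktransform.rotate(img, angle, resize=False, mode="reflect", order=1)
        out_boxes = [rotate_box(b, angle, h, w) for b in out_boxes]

    # horizontal flip of (on average) flip_probability of the images
    if config.flip_probability > 0 and rng.random() < config.flip_probability:
        img = img[:, ::-1]
        out_boxes = [flip_box_horizontal(b, w) for b in out_boxes]

    # isotropic rescale
    s_lo, s_hi = config.scale_range
    scale = float(rng.uniform(s_lo, s_hi)) if s_hi > s_lo else s_lo
    if scale != 1.0:
        img = sktransform.rescale(img, scale, channel_axis=-1 if img.ndim == 3 else None, order=1, mode="reflect", anti_aliasing=scale < 1.0)
        out_boxes = [_scale_box(b, scale) for b in out_boxes]

    # random crop retaining at least crop_min_fraction of the area,
    # then resize back to the configured output size
    ch, cw = img.shape[:2]
    if config.crop_enabled:
        keep = float(rng.uniform(math.sqrt(config.crop_min_fraction), 1.0))
        new_h = max(1, int(round(ch * keep)))
        new_w = max(1, int(round(cw * keep)))
        y_off = int(rng.integers(0, ch - new_h + 1))
        x_off = int(rng.integers(0, cw - new_w + 1))
        img = img[y_off : y_off + new_h, x_off : x_off + new_w]
        out_boxes = [b.shifted(-x_off, -y_off) for b in out_boxes]
        ch, cw = new_h, new_w

    if config.output_size is not None:
        target_h = target_w = int(config.output_size)
    else:
        target_h, target_w = h, w
    if (ch, cw) != (target_h, target_w):
        factor_y = target_h / ch
        factor_x = target_w / cw
        img = sktransform.resize(img, (target_h, target_w) + img.shape[2:], order=1, mode="reflect", anti_aliasing=max(factor_y, factor_x) < 1.0)
        out_boxes = [
            replace(
                b,
                x_min=b.x_min * factor_x,
                y_min=b.y_min * factor_y,
                x_max=b.x_max * factor_x,
                y_max=b.y_max * factor_y,
            )
            for b in out_boxes
        ]

    # clip to the output frame and drop boxes that lost too much area
    kept: list[BBox] = []
    n_dropped = 0
    for b, _area0 in zip(out_boxes, original_areas):
        clipped = _clip_box(b, target_h, target_w)
        if clipped is None:
            n_dropped += 1
            continue
        # area retained relative to the transformed (pre-clip) box: measures
        # loss from cropping/clipping only, invariant to legitimate zoom
        retained = clipped.area / b.area if b.area > 0 else 0.0
        if retained < config.min_box_area_fraction:
            n_dropped += 1
            continue
        kept.append(clipped)
    if n_dropped:
        logger.warning("augmentation dropped %d box(es) below the minimum visible area", n_dropped)

    if was_uint8:
        img = np.clip(img, 0.0, 1.0)

    # brightness: multiplier from [1 - f, 1 + f], clamped to the valid range
    f = config.brightness_max_factor
    if f > 0:
        factor = float(rng.uniform(1.0 - f, 1.0 + f))
        img = img * factor
        img = np.clip(img, 0.0, 1.0) if was_uint8 else img

    if was_uint8:
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img, kept
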