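"""Stage-1 presence classifier and stage-2 whale detector.

Both models sit behind backbone-agnostic train/predict contracts:

* the **presence classifier** maps a grid-cell patch to a probability
  simplex over (whale, ship, water + submerged rocks);
* the **detector** maps a patch to scored whale bounding boxes; the whale
  count is the number of boxes surviving score thresholding and
  non-maximum suppression.

The shipped defaults are deliberately small models trainable in seconds on
one CPU: a fixed statistical feature backbone feeding a two-layer
fully-connected head for classification, and a dense per-pixel scoring head
whose thresholded probability map yields boxes via connected components.
Heavier pretrained backbones can be plugged in through the same protocols —
the contracts never reference a specific architecture, only features in and
probabilities/boxes out.

Training uses RMSProp with momentum (momentum 0.9, squared-gradient decay
0.9, epsilon 0.1) and a stepped learning-rate schedule: the rate starts at
0.001 and is divided by a decay factor of 16 every 30 epochs.  In head-only
mode (the default, mirroring transfer-learning practice) only the final two
fully-connected parameter groups are trained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, transform as sktransform

from .scenes import CLASS_ORDER, CLASS_WHALE, BBox, box_iou

logger = logging.getLogger("whalescan")


class InvalidDatasetError(ValueError):
    """The training dataset violates a model's preconditions."""


# ---------------------------------------------------------------------------
# Training configuration and LR schedule
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Optimizer and schedule hyperparameters.

    The learning rate at (1-based) epoch ``e`` is
    ``learning_rate * decay_factor ** -((e - 1) // decay_every_epochs)``:
    epochs 1-30 run at 0.001, epochs 31-60 at 0.001/16, and so on.  The
    unusually large RMSProp epsilon (0.1) is deliberate and overridable.
    """

    learning_rate: float = 0.001
    decay_factor: float = 16.0
    decay_every_epochs: int = 30
    momentum: float = 0.9
    rms_decay: float = 0.9
    epsilon: float = 0.1
    epochs: int = 60
    batch_size: int = 32
    head_only: bool = True
    hidden_units: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if not self.decay_factor >= 1:
            raise ValueError("decay_factor must be >= 1")
        if not self.epochs >= 1:
            raise ValueError("epochs must be >= 1")
        if not self.decay_every_epochs >= 1:
            raise ValueError("decay_every_epochs must be >= 1")


def learning_rate_at(config: TrainingConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch index under the stepped schedule."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return config.learning_rate * config.decay_factor ** (
        -((epoch - 1) // config.decay_every_epochs)
    )


class RMSPropMomentum:
    """RMSProp with momentum (TensorFlow-style update).

    ms  <- rho * ms + (1 - rho) * g^2
    mom <- momentum * mom + lr * g / sqrt(ms + eps)
    w   <- w - mom
    """

    def __init__(self, params: list[np.ndarray], config: TrainingConfig):
        self.params = params
        self.config = config
        self.ms = [np.zeros_like(p) for p in params]
        self.mom = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        c = self.config
        for p, g, ms, mom in zip(self.params, grads, self.ms, self.mom):
            ms *= c.rms_decay
            ms += (1.0 - c.rms_decay) * g * g
            mom *= c.momentum
            mom += lr * g / np.sqrt(ms + c.epsilon)
            p -= mom


# ---------------------------------------------------------------------------
# Two-layer softmax head (the retrainable "last two fully connected layers")
# ---------------------------------------------------------------------------


class SoftmaxHead:
    """features -> FC(hidden) -> ReLU -> FC(classes) -> softmax."""

    def __init__(self, n_features: int, n_hidden: int, n_classes: int, rng: np.random.Generator):
        s1 = math.sqrt(2.0 / n_features)
        s2 = math.sqrt(2.0 / n_hidden)
        self.W1 = rng.normal(0.0, s1, (n_features, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, s2, (n_hidden, n_classes))
        self.b2 = np.zeros(n_classes)

    # parameter groups, in network order; the last two are the FC layers
    def param_groups(self) -> list[list[np.ndarray]]:
        return [[self.W1, self.b1], [self.W2, self.b2]]

    def flat_params(self, head_only: bool = True) -> list[np.ndarray]:
        groups = self.param_groups()
        trainable = groups[-2:]  # retrain only the two last FC layers
        return [p for g in trainable for p in g]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(0.0, X @ self.W1 + self.b1)
        logits = h @ self.W2 + self.b2
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, h

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, n_classes: int
    ) -> tuple[float, list[np.ndarray]]:
        n = X.shape[0]
        probs, h = self.forward(X)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        d_logits = probs.copy()
        d_logits[np.arange(n), y] -= 1.0
        d_logits /= n
        gW2 = h.T @ d_logits
        gb2 = d_logits.sum(axis=0)
        dh = d_logits @ self.W2.T
        dh[h <= 0.0] = 0.0
        gW1 = X.T @ dh
        gb1 = dh.sum(axis=0)
        return float(loss), [gW1, gb1, gW2, gb2]

    def state(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray]) -> "SoftmaxHead":
        obj = cls.__new__(cls)
        obj.W1 = np.asarray(state["W1"])
        obj.b1 = np.asarray(state["b1"])
        obj.W2 = np.asarray(state["W2"])
        obj.b2 = np.asarray(state["b2"])
        return obj


# ---------------------------------------------------------------------------
# Patch backbones (feature extractors for the presence classifier)
# ---------------------------------------------------------------------------


class PatchBackbone(Protocol):
    name: str

    def extract(self, patch: np.ndarray) -> np.ndarray:
        """Map an RGB uint8 patch to a 1-D feature vector."""


def _luminance(img: np.ndarray) -> np.ndarray:
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


class StatsBackbone:
    """Translation-invariant statistics plus blob-shape descriptors.

    Captures what separates the three survey classes in vertical ocean
    imagery: how much of the cell is brighter/darker than the local water
    level, how bright and how big the dominant blob is, whether it is
    elongated (whale, ship) or a ring of foam around a dark core (submerged
    rock), and coarse spatial layout.  No trainable parameters.
    """

    name = "stats-v2"

    @staticmethod
    def _blob_features(Ls: np.ndarray, base: float, mask: np.ndarray) -> list[float]:
        """Shape/contrast descriptors of the largest connected blob of a mask:
        coherence (largest component / mask size), area fraction,
        eccentricity, solidity, axis ratio, component count, mean contrast."""
        lab, n_comp = ndimage.label(mask)
        if n_comp == 0:
            return [0.0] * 7
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_comp + 1))
        blob = lab == (int(np.argmax(sizes)) + 1)
        props = measure.regionprops(blob.astype(np.uint8))[0]
        minor = max(props.axis_minor_length, 1e-6)
        return [
            float(sizes.max() / mask.sum()),
            float(blob.mean()),
            float(props.eccentricity),
            float(props.solidity),
            min(props.axis_major_length / minor, 20.0) / 20.0,
            min(n_comp, 12) / 12.0,
            float(Ls[blob].mean() - base),
        ]

    def extract(self, patch: np.ndarray) -> np.ndarray:
        if patch is None or patch.size == 0:
            raise ValueError("patch must be non-empty")
        img = np.asarray(patch, dtype=np.float64)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.max() > 1.5:
            img = img / 255.0
        L = _luminance(img)
        # median filter removes sub-pixel glint specks before blob analysis
        Lm = ndimage.median_filter(L, 3)
        Ls = ndimage.gaussian_filter(Lm, 1.5)
        base = float(np.median(Ls))

        feats: list[float] = []
        feats.extend(img.reshape(-1, 3).mean(axis=0))  # 3 channel means
        feats.extend(img.reshape(-1, 3).std(axis=0))  # 3 channel stds
        qs = np.percentile(L, [1, 5, 25, 50, 75, 95, 99])
        feats.extend(qs)  # 7 luminance quantiles
        feats.append(qs[6] - qs[3])  # bright tail
        feats.append(qs[3] - qs[0])  # dark tail

        # brightest-region blobs at fixed percentiles: always defined, so the
        # model can judge whether the brightest patch is a coherent object
        # (whale/ship/foam) or scattered wave crests
        for q in (90, 97):
            mask = Ls > np.percentile(Ls, q)
            bf = self._blob_features(Ls, base, mask)
            feats.extend(bf)
            feats.append(bf[0] * bf[6] * 50.0)  # coherence x contrast

        # absolute-contrast blobs: graded object brightness (whale body,
        # ship hull, breaking foam)
        for t in (0.04, 0.10, 0.20, 0.35):
            mask = Ls > base + t
            feats.append(float(mask.mean()))
            feats.extend(self._blob_features(Ls, base, mask) if mask.any() else [0.0] * 7)

        feats.append(float((Ls < base - 0.03).mean()))  # dark fraction (rock core)
        feats.append(float((L > 0.75).mean()))  # raw very-bright incl glint/foam
        gmag = np.hypot(ndimage.sobel(Ls, 0), ndimage.sobel(Ls, 1))
        feats.extend([float(gmag.mean()), float(gmag.std()), float(np.percentile(gmag, 95))])

        # ring score: dark pixels hugging the bright mask (foam around rock)
        bright = Ls > base + 0.10
        dark = Ls < base - 0.02
        if bright.any():
            near_bright = ndimage.binary_dilation(bright, iterations=3)
            feats.append(float((near_bright & dark).sum() / (bright.sum() + 1.0)))
        else:
            feats.append(0.0)

        return np.asarray(feats, dtype=np.float64)


class DownsampleBackbone:
    """Minimal alternative backbone: resized grayscale pixels as features."""

    name = "downsample-12"
    n_features = 144

    def extract(self, patch: np.ndarray) -> np.ndarray:
        if patch is None or patch.size == 0:
            raise ValueError("patch must be non-empty")
        img = np.asarray(patch, dtype=np.float64)
        if img.max() > 1.5:
            img = img / 255.0
        L = _luminance(img) if img.ndim == 3 else img
        small = sktransform.resize(L, (12, 12), order=1, mode="reflect", anti_aliasing=True)
        return small.ravel()


# ---------------------------------------------------------------------------
# Presence classifier
# ---------------------------------------------------------------------------


@dataclass
class ClassProbabilities:
    """Simplex over the three survey classes."""

    p_whale: float
    p_ship: float
    p_water_rock: float

    def __post_init__(self) -> None:
        total = self.p_whale + self.p_ship + self.p_water_rock
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_whale, self.p_ship, self.p_water_rock])

    @property
    def predicted_class(self) -> str:
        return CLASS_ORDER[int(np.argmax(self.as_array()))]


@dataclass
class Detection:
    """A scored whale bounding box."""

    box: BBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


class PresenceClassifier:
    """Three-class whale / ship / water+rock patch classifier."""

    kind = "presence"

    def __init__(
        self,
        backbone: PatchBackbone,
        head: SoftmaxHead,
        feature_mean: np.ndarray,
        feature_std: np.ndarray,
        config: TrainingConfig,
        training_log: list[dict] | None = None,
    ):
        self.backbone = backbone
        self.head = head
        self.feature_mean = feature_mean
        self.feature_std = feature_std
        self.config = config
        self.class_order = list(CLASS_ORDER)
        self.training_log = training_log or []

    def _features(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        X = np.stack([self.backbone.extract(p) for p in patches])
        return (X - self.feature_mean) / self.feature_std

    def classify(self, patch: np.ndarray) -> ClassProbabilities:
        if patch is None or np.size(patch) == 0:
            raise ValueError("patch must be non-empty")
        probs, _ = self.head.forward(self._features([patch]))
        p = probs[0]
        p = p / p.sum()
        return ClassProbabilities(p_whale=float(p[0]), p_ship=float(p[1]), p_water_rock=float(p[2]))

    def predict_labels(self, patches: Sequence[np.ndarray]) -> list[str]:
        probs, _ = self.head.forward(self._features(patches))
        return [CLASS_ORDER[i] for i in probs.argmax(axis=1)]

    def save(self, path: str | Path) -> None:
        _save_checkpoint(path, kind=self.kind, backbone=self.backbone.name, config=self.config,
                         arrays={"feature_mean": self.feature_mean, "feature_std": self.feature_std,
                                 **{f"head_{k}": v for k, v in self.head.state().items()}})

    @classmethod
    def load(cls, path: str | Path) -> "PresenceClassifier":
        meta, arrays = _load_checkpoint(path, expected_kind=cls.kind)
        return cls(
            backbone=_backbone_by_name(meta["backbone"]),
            head=SoftmaxHead.from_state({k[5:]: v for k, v in arrays.items() if k.startswith("head_")}),
            feature_mean=arrays["feature_mean"],
            feature_std=arrays["feature_std"],
            config=TrainingConfig(**meta["config"]),
        )


def _balanced_batches(
    labels_idx: np.ndarray, n_classes: int, batch_size: int, n_batches: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-balanced minibatch sampling (with replacement within class)."""
    by_class = [np.flatnonzero(labels_idx == c) for c in range(n_classes)]
    batches = []
    per = max(1, batch_size // n_classes)
    for _ in range(n_batches):
        parts = [rng.choice(idx, size=per, replace=True) for idx in by_class if len(idx)]
        batches.append(np.concatenate(parts))
    return batches


def _train_head(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    config: TrainingConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[SoftmaxHead, list[dict]]:
    rng = np.random.default_rng(config.seed)
    head = SoftmaxHead(X.shape[1], config.hidden_units, n_classes, rng)
    opt = RMSPropMomentum(head.flat_params(config.head_only), config)
    n_batches = max(1, math.ceil(len(y) / config.batch_size))
    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate_at(config, epoch)
        losses = []
        for batch in _balanced_batches(y, n_classes, config.batch_size, n_batches, rng):
            loss, grads = head.loss_and_grads(X[batch], y[batch], n_classes)
            opt.step(grads, lr)
            losses.append(loss)
        entry = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))}
        if X_val is not None and len(y_val):
            probs, _ = head.forward(X_val)
            entry["val_accuracy"] = float((probs.argmax(axis=1) == y_val).mean())
        log.append(entry)
    return head, log


def train_presence_classifier(
    dataset,
    config: TrainingConfig | None = None,
    backbone: PatchBackbone | None = None,
    val_dataset=None,
    n_augment: int = 3,
) -> PresenceClassifier:
    """Train the stage-1 three-class presence classifier.

    ``dataset`` needs ``patches`` and ``labels`` attributes (or may be a
    ``(patches, labels)`` tuple).  When the dataset carries a ``split``
    manifest, only its ``train`` rows are fitted and the ``val`` rows serve
    as the validation set (unless ``val_dataset`` overrides them).  Each
    training patch additionally contributes ``n_augment`` randomly augmented
    copies (rotation, flip, crop, rescale, brightness).  All three classes
    must be present.  Deterministic given the config seed.  The training log
    (per-epoch loss, realized learning rate, validation accuracy when a
    validation set is available) is available as ``classifier.training_log``.
    """
    from .augment import AugmentConfig, augment_patch

    config = config or TrainingConfig()
    backbone = backbone or StatsBackbone()
    patches, labels = _unpack_dataset(dataset)
    split = list(getattr(dataset, "split", [])) or ["train"] * len(patches)
    if len(split) != len(patches):
        raise InvalidDatasetError("split manifest length does not match the patches")
    if val_dataset is None and "val" in split:
        val_dataset = (
            [p for p, s in zip(patches, split) if s == "val"],
            [l for l, s in zip(labels, split) if s == "val"],
        )
    patches = [p for p, s in zip(patches, split) if s == "train"]
    labels = [l for l, s in zip(labels, split) if s == "train"]
    present = set(labels)
    missing = [c for c in CLASS_ORDER if c not in present]
    if missing:
        raise InvalidDatasetError(f"training data is missing class(es): {missing}")

    if n_augment > 0:
        aug_patches: list[np.ndarray] = []
        aug_labels: list[str] = []
        for i, (p, lab) in enumerate(zip(patches, labels)):
            for k in range(n_augment):
                cfg = AugmentConfig(seed=config.seed + 9973 * i + k)
                img, _ = augment_patch(p, [], cfg)
                aug_patches.append(img)
                aug_labels.append(lab)
        patches = patches + aug_patches
        labels = labels + aug_labels

    X_raw = np.stack([backbone.extract(p) for p in patches])
    mean = X_raw.mean(axis=0)
    std = X_raw.std(axis=0)
    std[std < 1e-8] = 1.0
    X = (X_raw - mean) / std
    y = np.array([CLASS_ORDER.index(lab) for lab in labels])

    X_val = y_val = None
    if val_dataset is not None:
        v_patches, v_labels = _unpack_dataset(val_dataset)
        if len(v_patches):
            X_val = (np.stack([backbone.extract(p) for p in v_patches]) - mean) / std
            y_val = np.array([CLASS_ORDER.index(lab) for lab in v_labels])

    head, log = _train_head(X, y, len(CLASS_ORDER), config, X_val, y_val)
    return PresenceClassifier(backbone, head, mean, std, config, training_log=log)


def _unpack_dataset(dataset) -> tuple[list[np.ndarray], list[str]]:
    if hasattr(dataset, "patches") and hasattr(dataset, "labels"):
        return list(dataset.patches), list(dataset.labels)
    patches, labels = dataset
    return list(patches), list(labels)


# ---------------------------------------------------------------------------
# Non-maximum suppression
# ---------------------------------------------------------------------------


def nms(detections: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression, highest score first.

    Idempotent: a second pass over the output changes nothing.  Ties in
    score are broken by input order for determinism.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in [0, 1]")
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    kept: list[Detection] = []
    for i in order:
        cand = detections[i]
        if all(box_iou(cand.box, k.box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Pixel-scoring detector
# ---------------------------------------------------------------------------


class PixelFeatureExtractor(Protocol):
    name: str

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Map an RGB uint8 image to an (H, W, F) feature stack."""


class ContrastPixelBackbone:
    """Per-pixel multi-scale contrast features against the local water level.

    A whale body reads as a coherent patch brighter than the surrounding
    water across several smoothing scales; wave texture decorrelates as the
    scale grows.  Features: signed contrast of the raw and Gaussian-smoothed
    luminance (sigma 1, 2, 4) against the image median, the local standard
    deviation, and the smoothed gradient magnitude.
    """

    name = "contrast-v1"
    n_features = 6

    def extract(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.max() > 1.5:
            img = img / 255.0
        L = _luminance(img)
        base = float(np.median(L))
        g1 = ndimage.gaussian_filter(L, 1.0)
        g2 = ndimage.gaussian_filter(L, 2.0)
        g4 = ndimage.gaussian_filter(L, 4.0)
        local_sq = ndimage.gaussian_filter(L * L, 2.0)
        local_std = np.sqrt(np.clip(local_sq - g2 * g2, 0.0, None))
        gmag = np.hypot(ndimage.sobel(g1, 0), ndimage.sobel(g1, 1))
        return np.stack([L - base, g1 - base, g2 - base, g4 - base, local_std, gmag], axis=-1)


class WhaleDetector:
    """Dense pixel-scoring detector: probability map -> components -> boxes.

    The per-pixel head scores whale-body membership; pixels at or above the
    mask threshold are grouped into connected components, each component
    yields one box (its bounding rectangle) scored by the component's mean
    probability.  Thresholding and NMS follow at detect time.
    """

    kind = "detector"

    def __init__(
        self,
        backbone: PixelFeatureExtractor,
        head: SoftmaxHead,
        feature_mean: np.ndarray,
        feature_std: np.ndarray,
        config: TrainingConfig,
        mask_threshold: float = 0.5,
        min_area_px: int = 4,
        training_log: list[dict] | None = None,
    ):
        self.backbone = backbone
        self.head = head
        self.feature_mean = feature_mean
        self.feature_std = feature_std
        self.config = config
        self.mask_threshold = mask_threshold
        self.min_area_px = min_area_px
        self.training_log = training_log or []

    def probability_map(self, image: np.ndarray) -> np.ndarray:
        if image is None or np.size(image) == 0:
            raise ValueError("image must be non-empty")
        feats = self.backbone.extract(image)
        H, W, F = feats.shape
        X = (feats.reshape(-1, F) - self.feature_mean) / self.feature_std
        probs, _ = self.head.forward(X)
        return probs[:, 1].reshape(H, W)

    def detect(
        self,
        image: np.ndarray,
        score_threshold: float = 0.5,
        nms_iou: float = 0.5,
    ) -> list[Detection]:
        if not (0.0 <= score_threshold <= 1.0) or not (0.0 <= nms_iou <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        pmap = self.probability_map(image)
        img = np.asarray(image, dtype=np.float64)
        L = img.mean(axis=2) if img.ndim == 3 else img
        if L.max() > 1.5:
            L = L / 255.0
        contrast = ndimage.gaussian_filter(L, 1.0) - float(np.median(L))
        mask = pmap >= self.mask_threshold
        lab, n_comp = ndimage.label(mask)
        detections: list[Detection] = []
        for region in range(1, n_comp + 1):
            comp = lab == region
            if comp.sum() < self.min_area_px:
                continue
            score = float(pmap[comp].mean())
            if score < score_threshold:
                continue
            # The smoothed features bleed probability a few pixels past the
            # object edge, and the bleed widens with object contrast, so the
            # raw component rectangle over-sizes bright targets.  Box the
            # luminous core instead: pixels whose brightness over the scene
            # median exceeds half the component peak, floored at an absolute
            # 0.05 so a bright blow does not crowd out the dimmer body
            # alongside it.
            cpk = float(contrast[comp].max())
            core = comp & (contrast >= min(0.5 * cpk, 0.05))
            ys, xs = np.nonzero(core if core.any() else comp)
            detections.append(
                Detection(
                    box=BBox(
                        x_min=float(xs.min()),
                        y_min=float(ys.min()),
                        x_max=float(xs.max()) + 1.0,
                        y_max=float(ys.max()) + 1.0,
                        class_label=CLASS_WHALE,
                        score=score,
                    ),
                    score=score,
                )
            )
        return nms(detections, nms_iou)

    def save(self, path: str | Path) -> None:
        _save_checkpoint(path, kind=self.kind, backbone=self.backbone.name, config=self.config,
                         extra={"mask_threshold": self.mask_threshold, "min_area_px": self.min_area_px},
                         arrays={"feature_mean": self.feature_mean, "feature_std": self.feature_std,
                                 **{f"head_{k}": v for k, v in self.head.state().items()}})

    @classmethod
    def load(cls, path: str | Path) -> "WhaleDetector":
        meta, arrays = _load_checkpoint(path, expected_kind=cls.kind)
        return cls(
            backbone=_pixel_backbone_by_name(meta["backbone"]),
            head=SoftmaxHead.from_state({k[5:]: v for k, v in arrays.items() if k.startswith("head_")}),
            feature_mean=arrays["feature_mean"],
            feature_std=arrays["feature_std"],
            config=TrainingConfig(**meta["config"]),
            mask_threshold=meta["extra"]["mask_threshold"],
            min_area_px=meta["extra"]["min_area_px"],
        )


def train_detector(
    dataset,
    config: TrainingConfig | None = None,
    backbone: PixelFeatureExtractor | None = None,
    pixels_per_image: int = 1200,
    positive_fraction: float = 0.33,
) -> WhaleDetector:
    """Train the stage-2 whale detector on box-annotated patches.

    ``dataset`` needs ``images`` and ``boxes`` attributes (or may be an
    ``(images, boxes)`` tuple).  Pixel-level supervision is derived from the
    boxes: pixels inside the central region of a whale box are positives,
    pixels well away from every box are negatives.  Images without boxes are
    allowed and contribute negatives only.
    """
    config = config or TrainingConfig()
    backbone = backbone or ContrastPixelBackbone()
    if hasattr(dataset, "images") and hasattr(dataset, "boxes"):
        images, boxes = list(dataset.images), list(dataset.boxes)
    else:
        images, boxes = dataset
        images, boxes = list(images), list(boxes)
    if not images:
        raise InvalidDatasetError("detector training set is empty")
    for img in images:
        if img is None or np.ndim(img) < 2:
            raise InvalidDatasetError("every training image needs pixel data with a known size")

    rng = np.random.default_rng(config.seed)
    X_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    n_pos_target = max(1, int(pixels_per_image * positive_fraction))
    n_neg_target = pixels_per_image - n_pos_target

    for img, bxs in zip(images, boxes):
        feats = backbone.extract(img)
        H, W, F = feats.shape
        lum = np.asarray(img, dtype=np.float64)
        lum = lum.mean(axis=2) if lum.ndim == 3 else lum
        if lum.max() > 1.5:
            lum = lum / 255.0
        lum_base = float(np.median(lum))
        pos_mask = np.zeros((H, W), dtype=bool)
        excl_mask = np.zeros((H, W), dtype=bool)
        for b in bxs:
            x0, y0 = int(math.floor(b.x_min)), int(math.floor(b.y_min))
            x1, y1 = int(math.ceil(b.x_max)), int(math.ceil(b.y_max))
            # a box is the AABB of a rotated body, so much of it is water;
            # positives are the box pixels brighter than halfway between the
            # scene background and the box peak (i.e. the body itself)
            region = np.zeros((H, W), dtype=bool)
            region[max(0, y0) : y1, max(0, x0) : x1] = True
            peak = float(lum[region].max()) if region.any() else lum_base
            pos_mask |= region & (lum >= lum_base + 0.5 * (peak - lum_base))
            excl_mask[max(0, y0 - 3) : y1 + 3, max(0, x0 - 3) : x1 + 3] = True
        neg_mask = ~excl_mask
        flat = feats.reshape(-1, F)
        pos_idx = np.flatnonzero(pos_mask.ravel())
        neg_idx = np.flatnonzero(neg_mask.ravel())
        if len(pos_idx):
            take = rng.choice(pos_idx, size=min(n_pos_target, len(pos_idx)), replace=False)
            X_parts.append(flat[take])
            y_parts.append(np.ones(len(take), dtype=int))
        if len(neg_idx):
            # half the negatives are hard: the brightest background pixels
            # (glint, wave crests) that uniform sampling would rarely pick
            n_take = min(n_neg_target, len(neg_idx))
            n_hard = n_take // 2
            lum = np.asarray(img, dtype=np.float64)
            lum = lum.mean(axis=2) if lum.ndim == 3 else lum
            order = np.argsort(lum.ravel()[neg_idx])[::-1]
            hard = neg_idx[order[: max(n_hard * 4, n_hard)]]
            take_hard = rng.choice(hard, size=min(n_hard, len(hard)), replace=False)
            take_rand = rng.choice(neg_idx, size=n_take - len(take_hard), replace=False)
            take = np.concatenate([take_hard, take_rand])
            X_parts.append(flat[take])
            y_parts.append(np.zeros(len(take), dtype=int))

    X_raw = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if y.sum() == 0:
        raise InvalidDatasetError("no positive pixels: the dataset has no whale boxes")
    mean = X_raw.mean(axis=0)
    std = X_raw.std(axis=0)
    std[std < 1e-8] = 1.0
    X = (X_raw - mean) / std
    head, log = _train_head(X, y, 2, config)
    return WhaleDetector(backbone, head, mean, std, config, training_log=log)


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def _config_hash(config: TrainingConfig) -> str:
    return hashlib.sha1(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:12]


def _save_checkpoint(path, *, kind, backbone, config, arrays, extra=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": kind,
        "backbone": backbone,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "class_order": list(CLASS_ORDER),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _load_checkpoint(path, expected_kind: str):
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        arrays = {k: np.asarray(data[k]) for k in data.files if k != "__meta__"}
    if meta["kind"] != expected_kind:
        raise ValueError(f"checkpoint is a {meta['kind']!r} model, expected {expected_kind!r}")
    return meta, arrays


def _backbone_by_name(name: str) -> PatchBackbone:
    for cls in (StatsBackbone, DownsampleBackbone):
        if cls.name == name:
            return cls()
    raise ValueError(f"unknown patch backbone {name!r}")


def _pixel_backbone_by_name(name: str) -> PixelFeatureExtractor:
    if name == ContrastPixelBackbone.name:
        return ContrastPixelBackbone()
    raise ValueError(f"unknown pixel backbone {name!r}")


def save_training_log_csv(log: list[dict], path: str | Path) -> None:
    """Write the per-epoch training log as CSV (epoch, lr, loss, val metrics)."""
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    keys = sorted({k for row in log for k in row}, key=lambda k: (k != "epoch", k != "lr", k != "loss", k))
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(log)
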