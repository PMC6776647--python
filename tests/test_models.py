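"""Models: LR schedule closed form, training contracts, NMS, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from whalescan import (
    BBox,
    ClassProbabilities,
    Detection,
    InvalidDatasetError,
    PresenceClassifier,
    SceneSpec,
    TrainingConfig,
    WhaleDetector,
    box_iou,
    generate_scene,
    learning_rate_at,
    nms,
    train_detector,
    train_presence_classifier,
)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


def test_learning_rate_closed_form_defaults():
    cfg = TrainingConfig()
    for epoch in range(1, 31):
        assert learning_rate_at(cfg, epoch) == pytest.approx(0.001)
    for epoch in range(31, 61):
        assert learning_rate_at(cfg, epoch) == pytest.approx(0.001 / 16.0)
    assert learning_rate_at(cfg, 61) == pytest.approx(0.001 / 256.0)


def test_learning_rate_closed_form_general():
    rng = np.random.default_rng(0)
    for _ in range(200):
        lr0 = float(rng.uniform(1e-5, 1e-1))
        decay = float(rng.uniform(1.0, 32.0))
        every = int(rng.integers(1, 50))
        epoch = int(rng.integers(1, 500))
        cfg = TrainingConfig(learning_rate=lr0, decay_factor=decay, decay_every_epochs=every)
        expected = lr0 * decay ** (-((epoch - 1) // every))
        assert learning_rate_at(cfg, epoch) == pytest.approx(expected)


def test_learning_rate_rejects_epoch_zero():
    with pytest.raises(ValueError):
        learning_rate_at(TrainingConfig(), 0)


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(decay_factor=0.5)
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainingConfig(decay_every_epochs=0)


# ---------------------------------------------------------------------------
# ClassProbabilities / Detection value objects
# ---------------------------------------------------------------------------


def test_class_probabilities_simplex_and_argmax():
    with pytest.raises(ValueError):
        ClassProbabilities(0.5, 0.5, 0.5)
    p = ClassProbabilities(0.2, 0.7, 0.1)
    assert p.predicted_class == "ship"
    assert ClassProbabilities(0.6, 0.2, 0.2).predicted_class == "whale"
    assert ClassProbabilities(0.1, 0.2, 0.7).predicted_class == "water_rock"


def test_detection_score_bounds():
    with pytest.raises(ValueError):
        Detection(box=BBox(0, 0, 1, 1), score=1.2)


# ---------------------------------------------------------------------------
# Presence-classifier training contract
# ---------------------------------------------------------------------------


def test_train_presence_requires_all_classes():
    rng = np.random.default_rng(0)
    patches = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8) for _ in range(6)]
    labels = ["whale", "ship", "whale", "ship", "whale", "ship"]  # water_rock missing
    with pytest.raises(InvalidDatasetError):
        train_presence_classifier((patches, labels), TrainingConfig(epochs=1))


def test_training_log_records_schedule(presence_classifier):
    log = presence_classifier.training_log
    assert len(log) == 20
    assert [e["epoch"] for e in log] == list(range(1, 21))
    assert all(e["lr"] == pytest.approx(0.001) for e in log)
    assert all(np.isfinite(e["loss"]) for e in log)
    # a val split exists in the dataset, so validation accuracy is logged
    assert "val_accuracy" in log[-1]


def test_calibration_val_macro_f1(classification_dataset, presence_classifier):
    """60 patches/class, default backbone, 20 epochs: val macro-F1 >= 0.9."""
    ds = classification_dataset
    val = [(p, l) for p, l, s in zip(ds.patches, ds.labels, ds.split) if s == "val"]
    preds = presence_classifier.predict_labels([p for p, _ in val])
    truth = [l for _, l in val]
    f1s = []
    for cls in ("whale", "ship", "water_rock"):
        tp = sum(1 for p, t in zip(preds, truth) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(preds, truth) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(preds, truth) if p != cls and t == cls)
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    assert float(np.mean(f1s)) >= 0.9


def test_pure_sea_patch_classified_water_rock(presence_classifier):
    spec = SceneSpec(width_m=71, height_m=71, pixel_size=1.0, seed=1234)
    patch = generate_scene(spec).scene.image
    assert presence_classifier.classify(patch).predicted_class == "water_rock"


def test_classifier_save_load_round_trip(presence_classifier, classification_dataset, tmp_path):
    path = tmp_path / "clf.npz"
    presence_classifier.save(path)
    back = PresenceClassifier.load(path)
    for patch in classification_dataset.patches[:12]:
        a = presence_classifier.classify(patch)
        b = back.classify(patch)
        assert a.as_array() == pytest.approx(b.as_array())


def test_classifier_rejects_empty_patch(presence_classifier):
    with pytest.raises(ValueError):
        presence_classifier.classify(np.zeros((0, 0, 3), dtype=np.uint8))


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------


def _det(x0, y0, x1, y1, score):
    return Detection(box=BBox(x0, y0, x1, y1, class_label="whale"), score=score)


def test_nms_suppresses_overlap_keeps_disjoint():
    dets = [
        _det(0, 0, 10, 10, 0.9),
        _det(1, 1, 11, 11, 0.8),  # heavy overlap with first
        _det(50, 50, 60, 60, 0.7),
    ]
    kept = nms(dets, 0.5)
    assert [d.score for d in kept] == [0.9, 0.7]


def test_nms_tie_broken_by_input_order():
    dets = [_det(0, 0, 10, 10, 0.5), _det(2, 0, 12, 10, 0.5)]
    kept = nms(dets, 0.3)
    assert len(kept) == 1
    assert kept[0].box.x_min == 0


def test_nms_idempotent_property():
    rng = np.random.default_rng(13)
    for _ in range(50):
        dets = []
        for _ in range(int(rng.integers(0, 20))):
            x0, y0 = rng.uniform(0, 80, 2)
            dets.append(
                _det(x0, y0, x0 + rng.uniform(2, 20), y0 + rng.uniform(2, 20), float(rng.uniform(0, 1)))
            )
        thr = float(rng.uniform(0.0, 1.0))
        once = nms(dets, thr)
        twice = nms(once, thr)
        assert [(d.box.x_min, d.box.y_min, d.score) for d in twice] == [
            (d.box.x_min, d.box.y_min, d.score) for d in once
        ]
        # no surviving pair overlaps above the threshold
        for i, a in enumerate(once):
            for b in once[i + 1 :]:
                assert box_iou(a.box, b.box) <= thr
        # output is a subset of the input, sorted by descending score
        assert all(d in dets for d in once)
        assert [d.score for d in once] == sorted((d.score for d in once), reverse=True)


def test_nms_rejects_bad_threshold():
    with pytest.raises(ValueError):
        nms([], 1.5)


# ---------------------------------------------------------------------------
# Detector
# ---------------------------------------------------------------------------


def test_train_detector_rejects_empty_and_boxless():
    with pytest.raises(InvalidDatasetError):
        train_detector(([], []), TrainingConfig(epochs=1))
    rng = np.random.default_rng(0)
    imgs = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(3)]
    with pytest.raises(InvalidDatasetError):
        train_detector((imgs, [[], [], []]), TrainingConfig(epochs=1))


def test_detector_finds_single_whale(whale_detector):
    spec = SceneSpec(
        width_m=128,
        height_m=128,
        pixel_size=1.0,
        n_whales=1,
        posture_mix={"logging": 1.0, "blowing": 0.0, "breaching": 0.0, "peduncle": 0.0, "spyhopping": 0.0, "submerged": 0.0},
        seed=42,
    )
    syn = generate_scene(spec)
    dets = whale_detector.detect(syn.scene.image)
    assert dets, "a logging whale must be detected"
    gt = [b for b in syn.annotation.boxes if b.class_label == "whale"][0]
    assert max(box_iou(d.box, gt) for d in dets) >= 0.3


def test_detector_score_threshold_filters(whale_detector):
    spec = SceneSpec(width_m=128, height_m=128, pixel_size=1.0, n_whales=2, seed=11)
    img = generate_scene(spec).scene.image
    loose = whale_detector.detect(img, score_threshold=0.0)
    strict = whale_detector.detect(img, score_threshold=0.99)
    assert len(strict) <= len(loose)
    assert all(d.score >= 0.99 for d in strict)


def test_detector_rejects_bad_thresholds(whale_detector):
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    with pytest.raises(ValueError):
        whale_detector.detect(img, score_threshold=2.0)
    with pytest.raises(ValueError):
        whale_detector.detect(img, nms_iou=-0.1)


def test_detector_save_load_round_trip(whale_detector, tmp_path):
    path = tmp_path / "det.npz"
    whale_detector.save(path)
    back = WhaleDetector.load(path)
    spec = SceneSpec(width_m=96, height_m=96, pixel_size=1.0, n_whales=1, seed=17)
    img = generate_scene(spec).scene.image
    a = whale_detector.detect(img)
    b = back.detect(img)
    assert len(a) == len(b)
    for da, db in zip(a, b):
        assert da.score == pytest.approx(db.score)
        assert (da.box.x_min, da.box.y_min, da.box.x_max, da.box.y_max) == (
            db.box.x_min,
            db.box.y_min,
            db.box.x_max,
            db.box.y_max,
        )


def test_checkpoint_kind_mismatch(presence_classifier, tmp_path):
    path = tmp_path / "clf.npz"
    presence_classifier.save(path)
    with pytest.raises(ValueError):
        WhaleDetector.load(path)
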