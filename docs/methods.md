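# Methods

This document describes the survey model implemented by `whalescan`, the
synthetic data it is exercised on, and the conventions used in every reported
number. All defaults quoted here are the package defaults; units are given with
each parameter.

## 1. Survey model

### 1.1 Grid tiling

A scene is a top-down RGB image with a known ground sampling distance
(`pixel_size`, metres per pixel) and an optional georeferenced origin. Scenes
are partitioned into square grid cells of `cell_size_m = 71 m` (the working
unit of the survey: small enough that a cell rarely holds more than one whale,
large enough to contain an adult whale with context). Cells are laid out
row-major from the top-left corner with stride equal to the cell size, so the
grid is a partition: every pixel belongs to exactly one cell. Edge cells that
extend past the image are padded (`pad_policy`, default `pad-reflect`;
`pad-zero` and `drop` are available).

Ground truth is assigned to cells by the **center rule**: an annotated box
belongs to the cell containing its center, so a whale straddling a border is
counted exactly once. A cell's class label is `whale` if it holds at least one
whale center, else `ship` if it holds a ship center, else `water_rock`.

### 1.2 Stage 1 — presence classification

Each cell patch is classified into `whale` / `ship` / `water_rock` by a small
model of the "frozen backbone, retrained head" form: a fixed, hand-designed
feature extractor followed by a trainable two-layer softmax head
(FC → ReLU(24 hidden units) → FC → softmax).

The default backbone (`stats-v2`, 34 features) summarizes a patch by
statistics chosen to separate the three classes at this scale: luminance
moments; glint-suppressed (3×3 median-filtered, σ = 1.5 Gaussian-smoothed)
blob descriptors at the 90th and 97th luminance percentiles and at four
absolute contrast levels (0.04, 0.10, 0.20, 0.35 above the scene median) —
each blob yielding coherence (largest component share), area fraction,
eccentricity, solidity, axis ratio, component count and mean contrast; a
coherence × contrast interaction; dark-pixel fraction; gradient statistics;
and a ring score that responds to the bow-wave/foam annulus around ships.

The head is trained with RMSProp with momentum (momentum 0.9, RMS decay 0.9,
epsilon 0.1, batch size 32) under a stepped learning-rate schedule:

```
lr(e) = learning_rate · decay_factor^(−⌊(e−1)/decay_every_epochs⌋)
```

with defaults `learning_rate = 0.001`, `decay_factor = 16`,
`decay_every_epochs = 30`, `epochs = 60`. Batches are class-balanced. When the
dataset carries a train/val split manifest, only the train rows are fitted and
validation accuracy is logged per epoch. Each training patch additionally
contributes `n_augment = 3` randomly augmented copies (section 3).

A cell **passes** stage 1 under the `threshold` rule (default) when
`p_whale ≥ presence_threshold = 0.5`; an `argmax` rule is also available.

### 1.3 Stage 2 — detection and counting

The detector scores every pixel of a passed cell for whale-body membership
using a per-pixel contrast backbone (signed contrast of raw and Gaussian-
smoothed luminance at σ = 1, 2, 4 against the image median, local standard
deviation, smoothed gradient magnitude) and the same trainable head. Pixels at
or above `mask_threshold = 0.5` are grouped into connected components;
components smaller than `min_area_px = 4` are dropped; each surviving
component becomes one box scored by its mean probability.

Because the smoothed features bleed probability past the object edge — and the
bleed widens with object contrast — the raw component rectangle over-sizes
bright targets. Boxes are therefore drawn around the component's **luminous
core**: the pixels whose smoothed luminance above the scene median exceeds
`min(0.5 · component peak contrast, 0.05)`. The absolute 0.05 floor keeps a dim
body in the box alongside its bright blow.

Detections below `score_threshold = 0.5` are discarded and greedy NMS at
`nms_iou = 0.5` removes duplicates within a cell. Across cells, fragments of
one whale split by a cell border are disjoint (plain NMS cannot join them), so
boxes that overlap or come within `merge_touch_px = 2` pixels are unioned
first (keeping the top score), then a final NMS at
`cross_cell_merge_iou = 0.5` runs in scene coordinates. The merged boxes are
the whale count.

Detector training derives pixel supervision from boxes: positives are the
bright pixels inside a whale box (luminance at least halfway from the scene
median to the box peak), negatives are pixels well away from every box, half
of them mined from the brightest background pixels so the model learns to
reject glint and foam rather than merely darkness.

### 1.4 Baseline

`run_baseline` applies stage 2 to *every* cell with no stage-1 filter. It uses
the identical detector, thresholds and merging, so any difference in the
comparison is attributable to the presence filter alone.

## 2. Synthetic scene generator

The generator renders seeded, bit-deterministic ocean scenes: a base water
color with large-scale swell, fine ripple, pixel noise and optional specular
glint; whales as elongated elliptical bodies with posture-dependent contrast;
ships as bright elongated hulls with wake; rocks as irregular dark/bright
clutter belonging to the background class (no boxes).

Whale postures and their default body-contrast ranges (luminance above local
water, on a 0–1 scale):

| posture | contrast | surfaced fraction | plume |
|---|---|---|---|
| breaching | 0.20–0.40 | 1.0 | yes (splash) |
| logging | 0.15–0.30 | 0.9 | no |
| blowing | 0.12–0.25 | 0.8 | yes (blow) |
| peduncle | 0.20–0.35 (emerged part) | 0.45 | no |
| spyhopping | 0.18–0.30 (head only) | 0.25 | no |
| submerged | 0.015–0.05 | 0.0 | no |

Submerged animals sit near the water-clutter floor and are genuinely hard;
detectability is monotone in body contrast, giving the expected posture
ordering (surfaced postures detected most often, submerged and spyhopping
least).

Three calibration decisions matter for realism and are locked into the
defaults:

- **Clutter floor.** Sea-state texture amplitudes are set so that the
  brightest smoothed water structure stays below half the lowest logging
  contrast (and below 3× the lowest submerged contrast). Surfaced whales are
  separable in principle; submerged ones are marginal, as in real imagery.
- **Analytic swell normalization.** The swell field is normalized by its
  analytic expected amplitude (2σ√π for the Gaussian-mixture field used), not
  by the per-scene empirical standard deviation. Empirical normalization made
  small rendered patches statistically different from crops of large scenes
  (the same texture at different amplitude), which silently shifted the
  train/test distribution of stage 1.
- **Plume in the annotation box.** The ground-truth box covers the visible
  whale — body plus blow or splash — because an annotator would box what they
  see; the body-only segmentation mask is kept separately for pixel-level
  supervision and tests.

Dataset builders: `generate_classification_dataset` (balanced patches per
class; rock-bearing background patches are rendered oversized and randomly
cropped so partial rocks appear at patch edges, as they do in tiled scenes),
`generate_detection_dataset` (whale patches with boxes, 1.35 boxes per image
on average) and `generate_survey_scenes` (annotated scenes with Poisson counts
of whales, ships and rocks).

## 3. Augmentation recipe

Training augmentation (`AugmentConfig`): rotation uniform in 0–360°,
horizontal flip with probability 0.5, random crop to ≥ 0.7 of the side,
rescale 0.75–1.25×, brightness ±50 %. Box coordinates are transformed exactly
(rotated corners → axis-aligned hull, clipping at the frame); boxes reduced
below 25 % of their area are dropped. `IDENTITY_CONFIG` disables every
transform and reproduces the input bit-exactly, which the tests rely on.

## 4. Evaluation conventions

- **Truncated percentages.** Every reported percentage is
  `floor(fraction · 10⁴)/100` — truncated, not rounded — so rates printed next
  to integer counts are always mutually consistent.
- **Counting metrics.** Merged scene-level detections are matched to
  ground-truth whale boxes greedily (descending score) at **IoU ≥ 0.3**. The
  threshold is deliberately looser than the classic 0.5 because the target is
  a *count*, not a tight localization: a box that covers the animal's visible
  extent but also its blow or a sliver of wake still represents one correctly
  counted whale. Precision, recall and F1 follow from the matched pairs; an
  `optimal` assignment matcher is provided for analysis.
- **Posture detectability.** Each ground-truth whale is tallied as
  detected/missed under its posture tag; rates are truncated percentages.
- **Stage-1 confusion.** For cascade runs the cell-level 3×3 confusion matrix
  (rows true, columns predicted) and per-row misclassification rates are
  reported.
- **Cross-validation.** `kfold_evaluate` provides stratified k-fold splits
  (default use: k = 5) with per-fold metrics, mean and standard deviation.
- **Multi-site totals.** `aggregate_sites` sums per-site summaries; sites with
  uncertain photo-interpreted counts are excluded from the photo total and
  reported separately. Reports aggregated together must share a configuration
  hash unless explicitly forced.

## 5. Study conditions

The packaged defaults are the study conditions: 71 m cells, 0.5 m pixels
(1 m in the fast test configurations so one 71-pixel patch is one cell),
700 patches per class at full scale, the stage-1 pass threshold of 0.5, the
stepped learning-rate schedule above, and IoU 0.3 counting evaluation. The
test suite trains small surrogates (60–120 patches per class, 20 epochs) that
reach validation macro-F1 ≥ 0.9 under seed 0 and reproduce the qualitative
results — the cascade's large F1 advantage over the detector-alone baseline
driven by false-positive suppression, and the posture-detectability ordering —
in minutes on one CPU.

## 6. Limitations

- The backbones are hand-designed feature extractors standing in for deep
  CNN features; they transfer the *structure* of the pipeline, not the
  capacity of a large pretrained network.
- The generator renders stylized scenes: no clouds, wave crests are isotropic
  texture rather than directional breaking seas, and ships are single hulls
  without superstructure detail.
- Counting assumes whales do not overlap within a cell; two touching animals
  merge into one detection.
- Georeferencing supports only a linear north-up pixel-to-world mapping.
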