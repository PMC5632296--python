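# Methods

## Pipeline model

`tipscan` frames feature localization as patch classification: a small CNN
decides whether a fixed-size window contains a feature (root tip; leaf/ear
tip/base), and localization emerges from scanning that classifier across the
image on a stride-4 grid. Tip coordinates are recovered from the resulting
probability map by thresholding, binary erosion and connected-component
centroids, and root-system traits are computed from tip coordinates alone.
The approach assumes features are visible within a single window (32 px for
roots, 64 px for shoots), that training annotations are point-accurate, and
that a feature's surroundings — not its exact centring — carry enough signal
for classification, which is why training jitters crops off-centre.

## Patch datasets

* Window sizes: 32 px (root) and 64 px (shoot); storage crops 42 px and
  128 px. Root training takes a uniformly random 32² sub-crop of the 42²
  patch each time a sample is drawn (offsets 0..10 in x and y); validation
  and scanning use the central crop. Shoot patches are reduced 128→64 by
  exact 2× area averaging (`downscale_local_mean`); the reduction method is
  a package choice.
* Root tips with a bearing-root arc length ≤ 16 px (half the window) are
  not used as positives: such short laterals are visually ambiguous with
  root hairs.
* Negatives per positive: 2:1 for roots, 1:1 for shoots. Root negatives are
  half arc-length-uniform samples on the known root polylines (hard
  negatives: root material that is not a tip) and half uniform over the
  image. Shoot negatives are Harris-corner candidates (clutter, plant
  material) with a 10% truly-random share so plain background is
  represented; the 10% figure is a package default, exposed in
  `DatasetConfig.random_negative_fraction`.
* Exclusion radius for negative centres: window/2 around every positive
  annotation — the same radius used when scoring localization. Border crops
  are completed by edge replication rather than discarded, so image-margin
  tips are not under-represented.
* The 80/20 train/validation split is a seeded random partition with
  `len(train) = floor(0.8 N)`.

## Classifiers

Both networks use unpadded 3×3 convolutions, 2×2 max pooling, ReLU after
every convolution and hidden dense layer, and 50% dropout between the three
fully connected layers. Unpadded convolutions are what make the layer counts
reduce the spatial side to exactly 1×1 before the dense stack:

* root: 32→30→28→(pool)14→12→10→(pool)5→3→1, filters 64, 64, 128, 128, 256,
  256, dense 256→64→2;
* shoot: 64→62→60→(pool)30→28→26→24→(pool)12→10→8→6→(pool)3→1, filters
  64, 64 | 128, 128, 128 | 256, 256, 256 | 512, dense 512→128→5.

The filter ramp doubles after each pooling stage; the dense widths follow
the deepest convolution. `base_filters` scales all widths proportionally
without changing the topology — reduced widths are how the desk-scale runs
train in minutes on one CPU.

Training is mini-batch SGD with momentum 0.9 and weight decay 5e-4
(conventional values for this family of networks; the optimizer choice is a
package decision), batch 64, fan-in-scaled ("He") Gaussian initialization.
The learning-rate schedule is stepped: divide by 10 every
`lr_decay_interval` iterations, default 20 000 from an initial 0.1 at full
scale. Validation accuracy is measured every `val_interval` iterations and
training stops once the best accuracy over the last `early_stop_patience`
checks exceeds the previous best by no more than 0.1 percentage points (the
"steady state" stop); the best checkpoint is returned. A non-finite loss
aborts with `TrainingDivergedError`.

### Input preprocessing and scaling

Inputs are 8-bit pixels minus the per-dataset mean colour, multiplied by a
fixed `input_scale` (default 1/128). The scale factor is a numerical
necessity, not a modelling choice: with fan-in-scaled initialization,
activation magnitudes track the input scale, and mean-centred raw pixels
(±O(100)) saturate the softmax so severely that the first updates at any
learning rate near the stepped schedule destroy the network (dead ReLUs,
constant output). Scaling to roughly unit range restores the regime in which
learning rates of order 0.1–0.01 behave. The scale is stored with the model
so inference is self-contained.

## Localization

The scan evaluates fully interior windows only; the map is smaller than the
image and annotations within window/2 of the border are unlocalizable by
construction. Cell (i, j) maps to image point (window/2 + stride·j,
window/2 + stride·i); the mapping round-trips exactly. The default
likelihood threshold is 0.5 and is configuration-exposed — only the
existence of a threshold, not its value, is inherent to the method. Batched
evaluation is numerically identical to per-window classification (regression
tested).

## Tip extraction

Threshold → binary erosion (full 3×3 structuring element) → 8-connected
component labelling → unweighted centroid per component → image coordinates.
Erosion operates on the stride-resolution grid, i.e. directly on the scan
output. The default is 3 iterations. The desk-scale synthetic study uses
1 iteration: with a 32 px window at stride 4, an above-threshold blob around
a tip spans only ~4–8 grid cells, and three erosions annihilate regions
thinner than 7 cells; one iteration removes single-cell artefacts (the
purpose of the step) without erasing genuine tips at this geometry. At
higher image resolutions, where blobs are wider, more iterations become
appropriate — the parameter is a compromise between noise removal and tip
loss, and is exposed everywhere.

## Traits

All traits are functions of the tip point set, in pixels. The seed position
is estimated as the mid-point of the top edge of the tips' bounding box
(smallest y). Strip counts use `seed_y < y ≤ seed_y + K` for
K ∈ {100, 200, 300} px; ties at the seed row count in no strip. Standard
deviations are population (n denominator). The width:depth ratio is NA only
when depth is 0 (e.g. a single tip); a zero width over positive depth is a
legitimate 0. Convex hulls of fewer than 3 or collinear points have area 0
by convention. "Mean X/Y" and "Centre of mass X/Y" are computed identically
but exported as separate columns for fidelity to the published trait list.
An optional mm/px multiplier rescales lengths and areas; strip counts keep
their pixel definition. The exported CSV has one row per image, columns in
the documented fixed order, `NA` for missing values.

## Evaluation metrics

Classification accuracy is `100 · Σcorrect / Σ(correct + misclassified)`
over a chosen class subset, reported to one decimal. Localization is scored
on the scan grid: every cell is a unit, the radius is half the window, FP%
counts positive cells farther than the radius from all truth points, FN%
counts in-radius cells that are not positive (the literal all-cells reading;
a per-feature hit/miss reading would be an alternative), and
`feature accuracy = 100 − FP% − FN%` holds exactly before rounding.
Point-level detection quality (used by the synthetic study) counts a truth
tip as recovered when a detected centroid lies within the radius, and a
detection as spurious when no truth tip is within the radius.

## Synthetic scenes

The root generator emulates pouch-grown seedling imagery: a light background
with Gaussian intensity noise (σ = 5 by default), dark anti-aliased root
strokes ~2 px half-width, primaries walking downward from a top-centre
source point with heading jitter (curvature 0.12 rad/step), laterals
branching at random arc positions. Roots are clamped to a 24 px margin so
annotated tips stay localizable by interior windows. Laterals drawn shorter
than 16 px are deliberately left unannotated, reproducing the root-hair
ambiguity that hard negative mining must survive. The shoot generator draws
green leaf strokes and thicker gold ear strokes over random bar/blob
clutter, annotating the four feature classes at stroke endpoints.

What the scenes do **not** emulate: real root-hair texture, overlapping root
crossings with occlusion, illumination gradients, camera noise statistics,
or photorealistic shoots. Passing the synthetic study therefore demonstrates
that the pipeline machinery (mining, training, scanning, morphology, traits)
is correct and self-consistent, not that the shipped default configuration
reaches real-image accuracy; full-scale accuracy on photographs requires
full-width networks and real annotated data.

## Desk-scale study conditions

`tipscan.pipeline.desk_scale_root_study` fixes the study size so it runs in
roughly ten minutes on one CPU: 130 training scenes (≈2 200 positive
patches, 2:1 negatives, ≈6 700 patches total), a width-8 root network
(`base_filters=8`), learning rate 0.01 stepped /10 every 2 000 iterations,
up to 4 000 iterations with the steady-state stop checked every 250, and 16
held-out evaluation scenes with sparser, well-separated tips, scanned at
stride 4, threshold 0.5, erosion 1 iteration. The reduced width and learning
rate are the proportional scaling of the full-size recipe; all other
parameters are the pipeline defaults.

## Known limitations

* The numpy engine is single-device and CPU-bound; full-width training at
  the published dataset sizes is out of its intended range.
* No rotation/flip augmentation, class re-weighting or fully convolutional
  inference; scanning cost grows linearly with image area.
* Tips closer together than the erosion/component resolution merge into one
  centroid; sub-stride localization refinement is not attempted.
* The seed-position estimate is derived from tips alone and absorbs
  horizontal root-system variation, so horizontally-referenced traits
  (e.g. centre of mass x) are less faithful than vertical ones.
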