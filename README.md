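# tipscan

Sliding-window CNN localization of plant features in 2-D images, with
root-system-architecture trait extraction for QTL discovery pipelines.

## The problem

High-throughput plant phenotyping needs feature coordinates, not just
classifications: where are the root tips in a washed-root seedling image,
where are the leaf and ear tips/bases in a cluttered shoot photograph?
Finding root tips is the rate-limiting step in 2-D root-system analysis, and
the traits derived from them (spread, depth, estimated total length) feed
directly into quantitative trait locus (QTL) mapping.

`tipscan` implements that pipeline end to end:

1. **Patch datasets** — square crops centred on annotated feature points
   become positives (root tips shorter than 16 px are excluded as
   root-hair-ambiguous); negatives are *hard-mined*: half on the known root
   system and half at random for roots (2 negatives per positive), Harris
   corner candidates plus a small random share for shoots (1:1). Crops are
   stored oversized (42 px for the 32 px root window; 128 px scaled to 64 for
   shoots) so random sub-cropping can jitter the feature off-centre during
   training. Data are split 80/20 into training and validation.
2. **Classifiers** — two small CNNs of unpadded 3×3 convolutions with 2×2 max
   pooling, ReLU throughout and 50% dropout between the three fully connected
   layers. The root net (input 32², 2 classes) traces
   32→30→28→14→12→10→5→3→1 spatially with filters ramping 64→256; the shoot
   net (input 64², 5 classes) uses convolution groups of 2/3/3 with a final
   conv, filters 64→512. Training is momentum SGD with a stepped learning
   rate (÷10 every 20 000 iterations at full scale) and mean-colour
   subtraction as input preprocessing; it halts at a validation-accuracy
   steady state.
3. **Localization** — the classifier slides over the full image at stride 4,
   producing a per-class probability map. Cell (i, j) corresponds exactly to
   the window centred at (16 + 4j, 16 + 4i).
4. **Tips** — the thresholded root-tip map is eroded with a 3×3 structuring
   element (removing single-cell artefacts and splitting touching tips),
   connected components are labelled (8-connectivity), and each component's
   centroid becomes a tip coordinate in image pixels.
5. **Traits** — from the tip set alone: tip count, convex-hull area,
   bounding-box width/depth and their ratio, mean and SD of tip positions,
   counts in the 100/200/300 px strips below the estimated seed position
   (mid-point of the top of the tips' bounding box), total length
   (Σ tip-to-seed distance) and centre of mass. Exported as a per-image CSV
   for QTL software; QTL model fitting itself is out of scope.
6. **Evaluation** — classification accuracy from per-class counts, and
   radius-based localization scores: with r = window/2, FP% is the share of
   map cells positive yet farther than r from every truth point, FN% the
   share within r of a truth point yet not positive, and
   feature accuracy = 100 − FP% − FN%.

Everything is testable without external data: `tipscan.fixtures` draws
synthetic root-system and shoot scenes with exact ground truth (annotated
tips, root polylines, a recorded seed point), deterministic under a seed.

## Worked example

```sh
python examples/traits_table.py
```

```
plant-01: 6 tips, hull 34950 px^2, w:d 0.53, total length 1442 px, seed (215, 60)
plant-02: 4 tips, hull 7800 px^2, w:d 0.39, total length 524 px, seed (200, 55)
plant-03: 7 tips, hull 54950 px^2, w:d 0.59, total length 1800 px, seed (210, 70)
trait table -> scratch/example_traits.csv
```

Each line is one plant's trait vector computed from its tip coordinates:
hull area measures root-system spread (px²), width:depth its shape (wide
vs deep), and total length approximates root-system size as the sum of
tip-to-seed distances. `examples/generate_scenes.py` shows the synthetic
scene generator and `examples/train_and_localize.py` trains a small detector
and localizes tips on a held-out scene.

The same stages are scriptable from the shell:

```sh
tipscan simulate --out ds --n 50 --seed 1
tipscan prepare  --manifest ds/manifest.json --out patches.npz --seed 1
tipscan train    --patches patches.npz --out model --seed 1
tipscan scan     --model model --manifest ds/manifest.json --out maps
tipscan tips     --maps maps --out tips.csv --iterations 1
tipscan traits   --tips tips.csv --out traits.csv
tipscan evaluate --tips tips.csv --manifest ds/manifest.json
```

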