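"""Train a small root-tip classifier and localize tips on a held-out scene.

A quick demonstration run: ~30 training scenes and a short schedule give a
usable (if not fully converged) detector in a couple of minutes on one CPU.
The full desk-scale study (tipscan.pipeline.desk_scale_root_study) uses 130
scenes and 4000 iterations.
"""

import numpy as np

from tipscan import fixtures, net, patchgen, pipeline
from tipscan.evalx import match_tips
from tipscan.locmap import scan_image
from tipscan.tips import extract_tips

train_scenes = fixtures.generate_root_scenes(30, 500, **pipeline.TRAIN_SCENE_KW)
dataset_cfg = patchgen.root_config(rng_seed=0)
train_cfg = net.TrainConfig(initial_lr=0.01, lr_decay_interval=600,
                            max_iterations=1200, val_interval=200, rng_seed=0)
model, summary = pipeline.train_root_detector(train_scenes, dataset_cfg,
                                              train_cfg, base_filters=8)
print(f"dataset: {summary['n_positive_patches']} tips + "
      f"{summary['n_negative_patches']} negatives "
      f"(train {summary['n_train']} / val {summary['n_val']})")
print(f"validation accuracy: {summary['val_accuracy_pct']:.1f}%")

scene = fixtures.generate_root_scenes(1, 9000, **pipeline.EVAL_SCENE_KW)[0]
cmap = scan_image(model, scene.raster, stride=4)
detected = extract_tips(cmap, "root_tip", threshold=0.5, iterations=1)
truth = pipeline.truth_tipset(scene)
recall, spurious = match_tips(detected.tips, truth.tips,
                              radius=model.spec.input_side / 2)
print(f"held-out scene: {len(truth)} true tips, {len(detected)} detected")
print(f"recall within half a window: {recall:.0f}%  "
      f"(spurious: {spurious:.0f}% of truth)")
# Recall counts a true tip as recovered when a detected centroid lies within
# 16 px (half the 32 px classification window) of the annotation.
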