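"""Generate synthetic annotated root scenes and write a dataset manifest.

Each scene is a light pouch-paper-style background with dark primary roots
growing downward and laterals branching off; every root is recorded as a
polyline and every qualifying tip as a point annotation, so downstream
stages can be scored against exact ground truth.
"""

from pathlib import Path

from tipscan.annot_io import write_manifest
from tipscan.fixtures import RootSceneParams, generate_root_image

scenes = [
    generate_root_image(RootSceneParams(n_primary=3, laterals_per_primary=(1, 3),
                                        lateral_length=(30.0, 70.0), seed=seed))
    for seed in range(5)
]

out = Path("scratch/example_scenes")
manifest = write_manifest(scenes, out)
print(f"wrote {len(scenes)} scenes -> {manifest}")
for img in scenes:
    n_tips = len(img.annotations)
    n_roots = len(img.polylines)
    print(f"  {img.image_id}: {n_roots} roots drawn, {n_tips} annotated tips, "
          f"seed position {tuple(round(v, 1) for v in img.seed_position)}")
# Tip counts differ between scenes because the number of laterals (and which
# of them exceed the 16 px annotation floor) is drawn per scene.
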