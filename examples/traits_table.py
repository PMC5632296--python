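"""Compute the root-trait table from tip coordinates.

Traits are derived purely from tip positions: the seed position is the
mid-point of the top of the tips' bounding box, strip counts look 100/200/300
pixels below it, and total length sums tip-to-seed distances.  The CSV this
writes is the hand-off point to QTL mapping software.
"""

from pathlib import Path

from tipscan.annot_io import write_trait_table
from tipscan.tips import TipSet
from tipscan.traits import compute_traits

# Tip sets for three plants (pixel coordinates, y downward).
plants = [
    TipSet("plant-01", [[210, 60], [150, 250], [260, 310], [180, 420],
                        [310, 380], [120, 330]]),
    TipSet("plant-02", [[200, 55], [190, 180], [240, 260], [160, 240]]),
    TipSet("plant-03", [[230, 70], [90, 300], [330, 290], [200, 480],
                        [280, 430], [140, 410], [250, 210]]),
]

records = [compute_traits(ts) for ts in plants]
for tv in records:
    print(f"{tv.image_id}: {tv.tip_count} tips, hull {tv.hull_area:.0f} px^2, "
          f"w:d {tv.width_depth_ratio:.2f}, total length {tv.total_length:.0f} px, "
          f"seed ({tv.seed_x:.0f}, {tv.seed_y:.0f})")

out = Path("scratch/example_traits.csv")
write_trait_table(records, out)
print(f"trait table -> {out}")
# hull area measures root-system spread; width:depth its shape; total length
# approximates overall root length from tip positions alone.
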