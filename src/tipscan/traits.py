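"""Root-system architecture traits computed from detected tip positions.

All traits derive from the tip point set alone.  The seed (source) position
is estimated as the mid-point of the top edge of the tips' bounding box —
consistent, if approximate, across images.  Units are pixels throughout; a
physical calibration (mm/px) can be applied as an optional multiplier.

Trait definitions:

* ``tip_count`` — number of detected tips (connected components).
* ``hull_area`` — area of the convex hull of the tip points (0 for fewer
  than 3 or collinear points).
* ``width`` / ``depth`` — bounding-box extents; ``width_depth_ratio`` is
  width/depth (NA when depth is 0).
* ``mean_x/y``, ``sd_x/y`` — mean and population standard deviation of tip
  coordinates.
* ``top100/200/300_count`` — tips in the 100/200/300-pixel strips below the
  estimated seed position.
* ``total_length`` — sum of Euclidean distances from each tip to the seed;
  a proxy for total root-system length.
* ``centre_mass_x/y`` — mean tip position (kept as separate columns from
  ``mean_x/y`` for fidelity to the published trait list).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .tips import TipSet


@dataclass
class TraitVector:
    """The per-image root-trait record (units: pixels, pixels²)."""

    image_id: str
    tip_count: int
    hull_area: float
    width: float
    depth: float
    width_depth_ratio: float  # NaN when depth == 0
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    top100_count: int
    top200_count: int
    top300_count: int
    total_length: float
    centre_mass_x: float
    centre_mass_y: float
    seed_x: float
    seed_y: float


def estimate_seed_position(tips: TipSet) -> tuple[float, float]:
    """Mid-point of the top edge of the bounding box around all tips.

    In the y-down convention the top edge is at the smallest y.
    Raises on an empty tip set.
    """
    if len(tips) == 0:
        raise ValueError("estimate_seed_position: empty TipSet")
    pts = tips.tips
    return (
        float((pts[:, 0].min() + pts[:, 0].max()) / 2.0),
        float(pts[:, 1].min()),
    )


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area; 0 by convention for <3 points or degenerate sets."""
    points = np.asarray(points, float).reshape(-1, 2)
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D: volume is the area
    except QhullError:
        return 0.0  # collinear


def compute_traits(tips: TipSet, mm_per_px: float = 1.0,
                   seed: tuple[float, float] | None = None) -> TraitVector:
    """Compute the full trait vector from a non-empty tip set.

    ``seed`` defaults to :func:`estimate_seed_position`.  ``mm_per_px``
    rescales lengths (and its square rescales areas) when a physical
    calibration is available; the default leaves everything in pixels.
    """
    if len(tips) == 0:
        raise ValueError("compute_traits: empty TipSet")
    pts = tips.tips
    if seed is None:
        seed = estimate_seed_position(tips)
    sx, sy = seed

    width = float(pts[:, 0].max() - pts[:, 0].min())
    depth = float(pts[:, 1].max() - pts[:, 1].min())
    ratio = width / depth if depth > 0 else float("nan")

    dy = pts[:, 1] - sy
    strip = lambda k: int(np.sum((dy > 0) & (dy <= k)))

    dist = np.hypot(pts[:, 0] - sx, pts[:, 1] - sy)

    s = mm_per_px
    return TraitVector(
        image_id=tips.image_id,
        tip_count=len(pts),
        hull_area=hull_area(pts) * s * s,
        width=width * s,
        depth=depth * s,
        width_depth_ratio=ratio,
        mean_x=float(pts[:, 0].mean()) * s,
        mean_y=float(pts[:, 1].mean()) * s,
        sd_x=float(pts[:, 0].std()) * s,  # population sd (n denominator)
        sd_y=float(pts[:, 1].std()) * s,
        # Strip counts are defined in image pixels by name; calibration does
        # not rescale them.
        top100_count=strip(100.0),
        top200_count=strip(200.0),
        top300_count=strip(300.0),
        total_length=float(dist.sum()) * s,
        centre_mass_x=float(pts[:, 0].mean()) * s,
        centre_mass_y=float(pts[:, 1].mean()) * s,
        seed_x=sx * s,
        seed_y=sy * s,
    )
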