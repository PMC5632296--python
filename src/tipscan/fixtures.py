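"""Synthetic annotated scenes with known ground truth.

Two generators are provided:

* :func:`generate_root_image` draws a seedling-style root system on a light,
  noisy background (the pouch-paper analogue): primary roots grow downward
  from a top-centre source point with jittered headings, laterals branch at
  random arc-length positions.  Every drawn root is returned as a polyline;
  tips of primaries, and of laterals whose arc length exceeds a configurable
  minimum, are annotated.  Short laterals are drawn but deliberately left
  unannotated — they emulate the root-hair ambiguity that hard-negative
  mining has to cope with.

* :func:`generate_shoot_image` draws leaf- and ear-like strokes against a
  cluttered background of random bars and blobs and annotates the four shoot
  feature classes (leaf tip/base, ear tip/base).  Clutter carries no
  annotations.

Both are deterministic: identical parameters and seed give byte-identical
rasters and annotation lists.  Coordinates are x-rightward, y-downward,
0-based pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annot_io import AnnotatedImage, PointAnnotation

#: Roots are kept at least this far (pixels) from the canvas border so that
#: annotated tips remain localizable by an interior sliding window.
DEFAULT_MARGIN = 24

#: Smallest classifier window the scenes are meant to serve; the canvas must
#: be at least four times this in each dimension.
MIN_WINDOW = 32


def _as_range(v) -> tuple[float, float]:
    """Accept a scalar or a (lo, hi) pair; a scalar is a degenerate range."""
    if np.isscalar(v):
        return float(v), float(v)
    lo, hi = v
    return float(lo), float(hi)


@dataclass
class RootSceneParams:
    """Parameters of a synthetic 2-D root-system scene.

    Lengths are in pixels.  ``laterals_per_primary`` and the two length
    fields accept either a scalar or an inclusive ``(lo, hi)`` range.
    ``curvature`` scales the per-step heading jitter (radians); ``min_annotate_length``
    is the arc-length floor below which a lateral is drawn but not annotated.
    """

    image_width: int = 256
    image_height: int = 256
    n_primary: int = 3
    laterals_per_primary: int | tuple[int, int] = 2
    primary_length: float | tuple[float, float] = (140.0, 200.0)
    lateral_length: float | tuple[float, float] = (30.0, 70.0)
    root_half_width: float = 2.0
    curvature: float = 0.12
    background_noise_sd: float = 5.0
    min_annotate_length: float = 16.0
    margin: int = DEFAULT_MARGIN
    seed: int = 0

    def validate(self) -> None:
        if self.n_primary < 0:
            raise ValueError("n_primary must be >= 0")
        lo, hi = _as_range(self.laterals_per_primary)
        if lo < 0:
            raise ValueError("laterals_per_primary must be >= 0")
        for name in ("primary_length", "lateral_length"):
            lo, hi = _as_range(getattr(self, name))
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive range")
        if min(self.image_width, self.image_height) < 4 * MIN_WINDOW:
            raise ValueError(
                f"canvas must be at least {4 * MIN_WINDOW} px in each dimension"
            )


@dataclass
class ShootSceneParams:
    """Parameters of a synthetic rotating-stage shoot scene."""

    image_width: int = 320
    image_height: int = 320
    n_leaves: int = 4
    n_ears: int = 1
    stroke_half_width: float = 2.5
    clutter_density: float = 40.0  # objects per megapixel
    margin: int = DEFAULT_MARGIN
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 0 or self.n_ears < 0:
            raise ValueError("counts must be >= 0")
        if self.clutter_density < 0:
            raise ValueError("clutter_density must be >= 0")
        if min(self.image_width, self.image_height) < 4 * MIN_WINDOW:
            raise ValueError(
                f"canvas must be at least {4 * MIN_WINDOW} px in each dimension"
            )


def _walk(start: np.ndarray, heading: float, length: float, curvature: float,
          rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray,
          step: float = 3.0) -> np.ndarray:
    """Random walk of roughly ``length`` arc length, clamped to [lo, hi] box."""
    pts = [start.copy()]
    pos = start.astype(float).copy()
    travelled = 0.0
    while travelled < length:
        heading += rng.normal(0.0, curvature)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, lo, hi)
        pts.append(pos.copy())
        travelled += step
    return np.asarray(pts)


def _stamp_polyline(alpha: np.ndarray, poly: np.ndarray, half_width: float) -> None:
    """Accumulate stroke coverage for ``poly`` into the alpha layer."""
    h, w = alpha.shape
    # Dense samples along the path, then a disk stamp at each sample.
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    r = max(half_width, 0.5)
    for (p, d, L) in zip(poly[:-1], seg, seglen):
        n = max(int(np.ceil(L)), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            cx, cy = p + t * d
            x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
            y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w), min(y1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            np.maximum(alpha[y0:y1, x0:x1], (d2 <= r * r).astype(np.float32),
                       out=alpha[y0:y1, x0:x1])


def _arc_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    d = np.diff(poly, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _point_at_arclength(poly: np.ndarray, s: float) -> tuple[np.ndarray, float]:
    """Point and local heading at arc length ``s`` along ``poly``."""
    d = np.diff(poly, axis=0)
    lens = np.hypot(d[:, 0], d[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(lens) - 1)
    frac = 0.0 if lens[i] == 0 else (s - cum[i]) / lens[i]
    pt = poly[i] + frac * d[i]
    heading = float(np.arctan2(d[i, 1], d[i, 0]))
    return pt, heading


def generate_root_image(params: RootSceneParams) -> AnnotatedImage:
    """Draw a synthetic root system; return raster + ground-truth annotations.

    Post-conditions: one ``root_tip`` annotation per primary and per lateral
    whose drawn arc length exceeds ``params.min_annotate_length``; a polyline
    per drawn root (annotated or not); the source point recorded as
    ``seed_position``.  Deterministic under ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, h = params.image_width, params.image_height
    m = params.margin
    lo = np.array([m, m], float)
    hi = np.array([w - 1 - m, h - 1 - m], float)

    source = np.array([w / 2 + rng.uniform(-8, 8), float(m)], float)

    polylines: list[np.ndarray] = []
    annotations: list[PointAnnotation] = []
    alpha = np.zeros((h, w), np.float32)

    lat_lo, lat_hi = _as_range(params.laterals_per_primary)
    plen_lo, plen_hi = _as_range(params.primary_length)
    llen_lo, llen_hi = _as_range(params.lateral_length)

    for _ in range(params.n_primary):
        heading = np.pi / 2 + rng.uniform(-0.45, 0.45)  # downward +/- ~26 deg
        length = rng.uniform(plen_lo, plen_hi)
        poly = _walk(source, heading, length, params.curvature, rng, lo, hi)
        polylines.append(poly)
        _stamp_polyline(alpha, poly, params.root_half_width)
        annotations.append(
            PointAnnotation("root_tip", x=float(poly[-1, 0]), y=float(poly[-1, 1]),
                            root_length=_arc_length(poly))
        )
        n_lat = int(rng.integers(int(lat_lo), int(lat_hi) + 1))
        arc = _arc_length(poly)
        for _ in range(n_lat):
            s = rng.uniform(0.2, 0.85) * arc
            branch, base_heading = _point_at_arclength(poly, s)
            side = rng.choice([-1.0, 1.0])
            lheading = base_heading + side * rng.uniform(0.6, 1.2)
            llen = rng.uniform(llen_lo, llen_hi)
            lpoly = _walk(branch, lheading, llen, params.curvature * 1.5, rng, lo, hi)
            polylines.append(lpoly)
            _stamp_polyline(alpha, lpoly, max(params.root_half_width - 0.5, 1.0))
            drawn = _arc_length(lpoly)
            if drawn > params.min_annotate_length:
                annotations.append(
                    PointAnnotation("root_tip", x=float(lpoly[-1, 0]),
                                    y=float(lpoly[-1, 1]), root_length=drawn)
                )

    # Soften stroke edges, then composite dark roots over the light paper.
    alpha = np.clip(gaussian_filter(alpha, 0.8), 0.0, 1.0)
    bg = 235.0 + rng.normal(0.0, params.background_noise_sd, (h, w))
    root_shade = 70.0 + rng.normal(0.0, 4.0, (h, w))
    grey = bg * (1.0 - alpha) + root_shade * alpha
    raster = np.clip(np.stack([grey, grey * 0.985, grey * 0.96], axis=-1),
                     0, 255).astype(np.uint8)

    img = AnnotatedImage(
        image_id=f"root-{params.seed}",
        raster=raster,
        annotations=annotations,
        polylines=polylines,
        seed_position=(float(source[0]), float(source[1])),
    )
    img.validate()
    return img


def _clutter(raster: np.ndarray, rng: np.random.Generator, density: float) -> None:
    """Draw random grey bars and blobs; purely background, never annotated."""
    h, w = raster.shape[:2]
    n = int(round(density * h * w / 1e6))
    for _ in range(n):
        shade = rng.uniform(30, 220)
        colour = np.array([shade, shade * rng.uniform(0.8, 1.0),
                           shade * rng.uniform(0.7, 1.0)])
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        if rng.random() < 0.5:  # bar
            ang = rng.uniform(0, np.pi)
            ln = rng.uniform(10, 60)
            hw = rng.uniform(1, 4)
            p0 = np.array([cx, cy])
            p1 = p0 + ln * np.array([np.cos(ang), np.sin(ang)])
            a = np.zeros((h, w), np.float32)
            _stamp_polyline(a, np.stack([p0, p1]), hw)
            raster[a > 0] = colour
        else:  # blob
            r = rng.uniform(2, 9)
            y0, y1 = int(max(cy - r, 0)), int(min(cy + r + 1, h))
            x0, x1 = int(max(cx - r, 0)), int(min(cx + r + 1, w))
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            raster[y0:y1, x0:x1][mask] = colour


def generate_shoot_image(params: ShootSceneParams) -> AnnotatedImage:
    """Draw leaf/ear strokes over clutter; annotate the four shoot classes."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, h = params.image_width, params.image_height
    m = params.margin
    lo = np.array([m, m], float)
    hi = np.array([w - 1 - m, h - 1 - m], float)

    base = rng.normal(200.0, 6.0, (h, w))
    raster = np.clip(np.stack([base, base, base * 0.98], axis=-1), 0, 255
                     ).astype(np.uint8)
    _clutter(raster, rng, params.clutter_density)

    annotations: list[PointAnnotation] = []

    def stroke(colour: np.ndarray, half_width: float, length: float,
               upward_bias: float) -> tuple[np.ndarray, np.ndarray]:
        start = np.array([rng.uniform(m, w - 1 - m), rng.uniform(h * 0.45, h - 1 - m)])
        heading = -np.pi / 2 + rng.uniform(-upward_bias, upward_bias)
        poly = _walk(start, heading, length, 0.08, rng, lo, hi)
        a = np.zeros((h, w), np.float32)
        _stamp_polyline(a, poly, half_width)
        a = np.clip(gaussian_filter(a, 0.8), 0, 1)
        for c in range(3):
            raster[..., c] = np.clip(
                raster[..., c] * (1 - a) + colour[c] * a, 0, 255
            ).astype(np.uint8)
        return poly[0], poly[-1]

    for _ in range(params.n_leaves):
        green = np.array([60.0, 150.0, 60.0]) + rng.normal(0, 10, 3)
        base_pt, tip_pt = stroke(green, params.stroke_half_width,
                                 rng.uniform(60, 120), 0.9)
        annotations.append(PointAnnotation("leaf_base", float(base_pt[0]), float(base_pt[1])))
        annotations.append(PointAnnotation("leaf_tip", float(tip_pt[0]), float(tip_pt[1])))

    for _ in range(params.n_ears):
        gold = np.array([190.0, 160.0, 70.0]) + rng.normal(0, 8, 3)
        base_pt, tip_pt = stroke(gold, params.stroke_half_width * 2.2,
                                 rng.uniform(40, 80), 0.4)
        annotations.append(PointAnnotation("ear_base", float(base_pt[0]), float(base_pt[1])))
        annotations.append(PointAnnotation("ear_tip", float(tip_pt[0]), float(tip_pt[1])))

    img = AnnotatedImage(
        image_id=f"shoot-{params.seed}",
        raster=raster,
        annotations=annotations,
    )
    img.validate()
    return img


def generate_root_scenes(n: int, base_seed: int, **overrides) -> list[AnnotatedImage]:
    """Generate ``n`` root scenes with distinct seeds ``base_seed + i``."""
    out = []
    for i in range(n):
        p = RootSceneParams(seed=int(base_seed) + i, **overrides)
        out.append(generate_root_image(p))
    return out
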