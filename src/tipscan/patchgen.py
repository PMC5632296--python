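"""Build balanced patch-classification datasets from annotated images.

Positives are square crops centred on annotated feature points.  Negatives are
mined hard: for root images, half on the known root system (polylines) and
half at random positions, always outside an exclusion radius around every tip;
for shoot images, mostly at Harris corner candidates (clutter and plant
material) plus a small random fraction.

Storage crops are larger than the classifier window (42 px stored for the
32 px root window; 128 px stored, scaled to 64, for shoots) so that random
sub-cropping can be applied as augmentation during training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import corner_harris, corner_peaks
from skimage.transform import downscale_local_mean

from .annot_io import AnnotatedImage, PointAnnotation

logger = logging.getLogger(__name__)

#: Label used for mined negative patches.
NEGATIVE_LABEL = "negative"

ROOT_CLASSES = ("root_tip", NEGATIVE_LABEL)
SHOOT_CLASSES = ("leaf_tip", "leaf_base", "ear_tip", "ear_base", NEGATIVE_LABEL)


@dataclass
class DatasetConfig:
    """Patch-dataset construction parameters.

    Defaults follow the root recipe; :func:`shoot_config` returns the shoot
    variant.  ``window_size`` is the classifier input side; ``storage_crop``
    the stored crop side; tips whose bearing root is not longer than
    ``min_root_length`` are excluded (root domain); ``negative_ratio`` is the
    number of mined negatives per positive; ``split_fraction`` the training
    share of the 80/20 split.
    """

    domain: str = "root"
    window_size: int = 32
    storage_crop: int = 42
    min_root_length: float = 16.0
    negative_ratio: float = 2.0
    split_fraction: float = 0.8
    random_negative_fraction: float = 0.1  # shoot domain: truly random share
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.storage_crop < self.window_size:
            raise ValueError("storage_crop must be >= window_size")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.domain not in ("root", "shoot"):
            raise ValueError("domain must be 'root' or 'shoot'")

    @property
    def exclusion_radius(self) -> float:
        """Negative centres must be farther than this from every annotation.

        Set to half the classification window, matching the radius used when
        scoring localization.
        """
        return self.window_size / 2.0

    @property
    def class_names(self) -> tuple[str, ...]:
        return ROOT_CLASSES if self.domain == "root" else SHOOT_CLASSES


def root_config(**overrides) -> DatasetConfig:
    """Root-domain defaults: 32 px window, 42 px storage, 2:1 negatives."""
    return replace(DatasetConfig(), **overrides)


def shoot_config(**overrides) -> DatasetConfig:
    """Shoot-domain defaults: 64 px window, 128 px storage, 1:1 negatives."""
    base = DatasetConfig(domain="shoot", window_size=64, storage_crop=128,
                         negative_ratio=1.0)
    return replace(base, **overrides)


@dataclass
class PatchSample:
    """A fixed-size crop with its label and provenance."""

    patch: np.ndarray  # side x side x 3 uint8
    label: str
    source_image_id: str
    source_xy: tuple[float, float]  # crop centre in source-image pixels


def crop_centred(raster: np.ndarray, x: float, y: float, side: int) -> np.ndarray:
    """Square crop of ``side`` centred at (x, y), edge-replicated at borders.

    The annotation lands on the crop pixel ``(side // 2, side // 2)``.
    """
    h, w = raster.shape[:2]
    cx, cy = int(round(x)), int(round(y))
    half = side // 2
    x0, y0 = cx - half, cy - half
    x1, y1 = x0 + side, y0 + side
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - w), max(0, y1 - h)
    crop = raster[max(y0, 0):min(y1, h), max(x0, 0):min(x1, w)]
    if pad_l or pad_t or pad_r or pad_b:
        crop = np.pad(crop, ((pad_t, pad_b), (pad_l, pad_r), (0, 0)), mode="edge")
    return crop


def extract_positive_patches(img: AnnotatedImage, cfg: DatasetConfig
                             ) -> list[PatchSample]:
    """One storage-size patch per qualifying annotation, centred on it.

    In the root domain, tips whose recorded ``root_length`` is not greater
    than ``cfg.min_root_length`` are excluded (short laterals are ambiguous
    with root hairs).  Border crops are completed by edge replication.
    """
    out: list[PatchSample] = []
    for a in img.annotations:
        if a.feature_class not in cfg.class_names:
            continue
        if (cfg.domain == "root" and a.root_length is not None
                and a.root_length <= cfg.min_root_length):
            continue
        patch = crop_centred(img.raster, a.x, a.y, cfg.storage_crop)
        out.append(PatchSample(patch, a.feature_class, img.image_id, (a.x, a.y)))
    return out


def _far_from_all(x: float, y: float, points: np.ndarray, radius: float) -> bool:
    if len(points) == 0:
        return True
    d2 = (points[:, 0] - x) ** 2 + (points[:, 1] - y) ** 2
    return bool(np.min(d2) > radius * radius)


def _annotation_points(img: AnnotatedImage) -> np.ndarray:
    return np.array([[a.x, a.y] for a in img.annotations], float).reshape(-1, 2)


def _sample_on_polylines(polylines: Sequence[np.ndarray],
                         rng: np.random.Generator) -> tuple[float, float]:
    """Arc-length-uniform sample over a set of polylines."""
    lens = []
    for p in polylines:
        d = np.diff(np.asarray(p, float), axis=0)
        lens.append(float(np.sum(np.hypot(d[:, 0], d[:, 1]))))
    total = sum(lens)
    if total == 0:
        p = np.asarray(polylines[0], float)
        return float(p[0, 0]), float(p[0, 1])
    s = rng.uniform(0, total)
    for p, L in zip(polylines, lens):
        if s > L:
            s -= L
            continue
        p = np.asarray(p, float)
        d = np.diff(p, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        i = min(int(np.searchsorted(cum, s, side="right") - 1), len(seg) - 1)
        frac = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
        pt = p[i] + frac * d[i]
        return float(pt[0]), float(pt[1])
    p = np.asarray(polylines[-1], float)
    return float(p[-1, 0]), float(p[-1, 1])


def mine_negatives_root(img: AnnotatedImage, n: int, cfg: DatasetConfig,
                        rng: np.random.Generator | None = None,
                        max_attempts_per_sample: int = 60) -> list[PatchSample]:
    """Mine ``n`` root-domain negatives: ceil(n/2) on-root + floor(n/2) random.

    On-root centres are sampled arc-length-uniformly over the polylines (hard
    negatives: root material that is not a tip); the rest are uniform over the
    image.  Every centre is farther than ``cfg.exclusion_radius`` from every
    tip annotation.  If the image cannot supply enough valid centres within
    the attempt budget, fewer samples are returned with a logged warning.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n_on_root = math.ceil(n / 2)
    n_random = n - n_on_root
    if n_on_root > 0 and not img.polylines:
        raise ValueError(
            f"{img.image_id}: on-root negative mining requires polylines"
        )
    pts = _annotation_points(img)
    h, w = img.shape
    out: list[PatchSample] = []

    def mine(count: int, draw: Callable[[], tuple[float, float]]) -> None:
        got, attempts = 0, 0
        while got < count and attempts < max_attempts_per_sample * count:
            attempts += 1
            x, y = draw()
            if not _far_from_all(x, y, pts, cfg.exclusion_radius):
                continue
            patch = crop_centred(img.raster, x, y, cfg.storage_crop)
            out.append(PatchSample(patch, NEGATIVE_LABEL, img.image_id, (x, y)))
            got += 1
        if got < count:
            logger.warning("%s: mined only %d/%d negatives", img.image_id, got, count)

    if n_on_root:
        mine(n_on_root, lambda: _sample_on_polylines(img.polylines, rng))
    if n_random:
        mine(n_random, lambda: (rng.uniform(0, w - 1), rng.uniform(0, h - 1)))
    return out


def harris_candidates(raster: np.ndarray, min_distance: int = 4,
                      threshold_rel: float = 0.02) -> np.ndarray:
    """Harris corner candidates as an (n, 2) array of (x, y) pixels."""
    grey = rgb2gray(raster)
    response = corner_harris(grey)
    peaks = corner_peaks(response, min_distance=min_distance,
                         threshold_rel=threshold_rel)  # rows of (y, x)
    if len(peaks) == 0:
        return np.empty((0, 2), float)
    return peaks[:, ::-1].astype(float)


def mine_negatives_shoot(img: AnnotatedImage, n: int, cfg: DatasetConfig,
                         rng: np.random.Generator | None = None) -> list[PatchSample]:
    """Mine ``n`` shoot-domain negatives from Harris corners plus random spots.

    A ``cfg.random_negative_fraction`` share is drawn at truly random
    positions (so plain background is represented); the rest are Harris
    corner candidates outside the exclusion radius of every annotation.  If
    there are too few candidates the shortfall falls back to random positions
    (logged).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    pts = _annotation_points(img)
    h, w = img.shape
    n_random = int(round(cfg.random_negative_fraction * n))
    n_hard = n - n_random

    cand = harris_candidates(img.raster)
    valid = [c for c in cand if _far_from_all(c[0], c[1], pts, cfg.exclusion_radius)]
    out: list[PatchSample] = []
    if valid:
        valid_arr = np.asarray(valid)
        take = min(n_hard, len(valid_arr))
        idx = rng.choice(len(valid_arr), size=take, replace=False)
        for i in idx:
            x, y = valid_arr[i]
            patch = crop_centred(img.raster, x, y, cfg.storage_crop)
            out.append(PatchSample(patch, NEGATIVE_LABEL, img.image_id,
                                   (float(x), float(y))))
    shortfall = n_hard - len(out)
    if shortfall > 0:
        logger.warning("%s: only %d Harris candidates; %d negatives fall back "
                       "to random positions", img.image_id, len(out), shortfall)
    need_random = n_random + max(shortfall, 0)
    got, attempts = 0, 0
    while got < need_random and attempts < 60 * max(need_random, 1):
        attempts += 1
        x, y = rng.uniform(0, w - 1), rng.uniform(0, h - 1)
        if not _far_from_all(x, y, pts, cfg.exclusion_radius):
            continue
        patch = crop_centred(img.raster, x, y, cfg.storage_crop)
        out.append(PatchSample(patch, NEGATIVE_LABEL, img.image_id, (x, y)))
        got += 1
    return out


def split_dataset(samples: Sequence, cfg: DatasetConfig) -> tuple[list, list]:
    """Seeded random 80/20 (``split_fraction``) partition.

    ``len(train) == floor(split_fraction * N)``; the remainder validates.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("split_dataset: samples must be non-empty")
    rng = np.random.default_rng(cfg.rng_seed)
    order = rng.permutation(len(samples))
    n_train = int(math.floor(cfg.split_fraction * len(samples)))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val


def compute_mean_color(train: Sequence[PatchSample]) -> tuple[float, float, float]:
    """Per-channel mean over every pixel of every training patch (0-255)."""
    train = list(train)
    if not train:
        raise ValueError("compute_mean_color: training set must be non-empty")
    sums = np.zeros(3, np.float64)
    count = 0
    for s in train:
        sums += s.patch.reshape(-1, 3).sum(axis=0)
        count += s.patch.shape[0] * s.patch.shape[1]
    mean = sums / count
    return float(mean[0]), float(mean[1]), float(mean[2])


def augment_for_training(sample: PatchSample, cfg: DatasetConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Reduce a storage crop to the classifier window.

    Root domain: a uniformly random ``window_size`` sub-crop of the storage
    crop (offsets in {0..storage-window}²) — the jitter augmentation that
    stops tips from always sitting dead-centre.  Shoot domain: deterministic
    area-weighted 2x downscale of the 128 px crop to 64 px.
    """
    patch = sample.patch
    if patch.shape[0] != cfg.storage_crop or patch.shape[1] != cfg.storage_crop:
        raise ValueError(
            f"expected {cfg.storage_crop}px storage crop, got {patch.shape[:2]}"
        )
    if cfg.domain == "root":
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        span = cfg.storage_crop - cfg.window_size
        ox = int(rng.integers(0, span + 1))
        oy = int(rng.integers(0, span + 1))
        return patch[oy:oy + cfg.window_size, ox:ox + cfg.window_size]
    factor = cfg.storage_crop // cfg.window_size
    down = downscale_local_mean(patch.astype(np.float64), (factor, factor, 1))
    return np.clip(np.rint(down), 0, 255).astype(np.uint8)


def center_crop(patch: np.ndarray, side: int) -> np.ndarray:
    """Central ``side`` crop — the deterministic counterpart of augmentation,
    used for validation and scanning in the root domain."""
    h, w = patch.shape[:2]
    oy, ox = (h - side) // 2, (w - side) // 2
    return patch[oy:oy + side, ox:ox + side]


def build_dataset(images: Sequence[AnnotatedImage], cfg: DatasetConfig,
                  ) -> tuple[list[PatchSample], list[PatchSample]]:
    """Positives + mined negatives for a set of images, split train/val.

    Negatives are mined per image at ``cfg.negative_ratio`` times that
    image's positive count, using the domain's mining strategy.  Returns
    ``(train, val)`` after the seeded split.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    samples: list[PatchSample] = []
    for img in images:
        pos = extract_positive_patches(img, cfg)
        samples.extend(pos)
        n_neg = int(round(cfg.negative_ratio * len(pos)))
        if n_neg == 0:
            continue
        if cfg.domain == "root":
            samples.extend(mine_negatives_root(img, n_neg, cfg, rng))
        else:
            samples.extend(mine_negatives_shoot(img, n_neg, cfg, rng))
    return split_dataset(samples, cfg)
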