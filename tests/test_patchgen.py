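"""Patch extraction, hard-negative mining, splitting and augmentation."""

import math

import numpy as np
import pytest
from scipy import stats

from tipscan import patchgen
from tipscan.annot_io import AnnotatedImage, PointAnnotation
from tipscan.fixtures import (RootSceneParams, ShootSceneParams,
                              generate_root_image, generate_shoot_image)
from tipscan.patchgen import (NEGATIVE_LABEL, augment_for_training,
                              compute_mean_color, extract_positive_patches,
                              harris_candidates, mine_negatives_root,
                              mine_negatives_shoot, root_config, shoot_config,
                              split_dataset)


@pytest.fixture(scope="module")
def scene():
    return generate_root_image(
        RootSceneParams(n_primary=3, laterals_per_primary=2,
                        lateral_length=(30.0, 60.0), seed=21))


# --- positives ---------------------------------------------------------------

def test_positive_patches_one_per_qualifying_tip(scene):
    cfg = root_config()
    patches = extract_positive_patches(scene, cfg)
    assert len(patches) == len(scene.annotations) == 9
    for p in patches:
        assert p.patch.shape == (42, 42, 3)
        assert p.label == "root_tip"


def test_positive_patch_centred_on_annotation(scene):
    cfg = root_config()
    for p in extract_positive_patches(scene, cfg):
        x, y = int(round(p.source_xy[0])), int(round(p.source_xy[1]))
        centre = p.patch[cfg.storage_crop // 2, cfg.storage_crop // 2]
        assert np.array_equal(centre, scene.raster[y, x])


def test_short_root_tips_excluded():
    raster = np.full((200, 200, 3), 230, np.uint8)
    img = AnnotatedImage("t", raster, [
        PointAnnotation("root_tip", 50, 50, root_length=40),
        PointAnnotation("root_tip", 80, 80, root_length=10),
        PointAnnotation("root_tip", 120, 120, root_length=16),  # floor: excluded
        PointAnnotation("root_tip", 150, 150, root_length=25),
    ])
    patches = extract_positive_patches(img, root_config())
    assert len(patches) == 2
    assert {p.source_xy for p in patches} == {(50, 50), (150, 150)}


def test_border_annotation_padded_to_full_size():
    raster = np.arange(200 * 200 * 3, dtype=np.uint8).reshape(200, 200, 3)
    img = AnnotatedImage("t", raster,
                         [PointAnnotation("root_tip", 0, 0, root_length=40)])
    (p,) = extract_positive_patches(img, root_config())
    assert p.patch.shape == (42, 42, 3)
    # Edge replication: the padded corner repeats the image corner pixel.
    assert np.array_equal(p.patch[0, 0], raster[0, 0])


# --- negatives ---------------------------------------------------------------

def test_root_negatives_split_half_on_root_half_random(scene):
    cfg = root_config()
    rng = np.random.default_rng(0)
    negs = mine_negatives_root(scene, 10, cfg, rng)
    assert len(negs) == 10
    assert all(n.label == NEGATIVE_LABEL for n in negs)
    # On-root samples (first ceil(n/2)) lie within the stroke width of a
    # polyline; verify by brute-force nearest-vertex distance.
    on_root = negs[:5]
    for n in on_root:
        x, y = n.source_xy
        dmin = min(float(np.min(np.hypot(p[:, 0] - x, p[:, 1] - y)))
                   for p in scene.polylines)
        assert dmin <= max(scene_half_width(scene), 3.0)


def scene_half_width(scene):
    return 2.0  # RootSceneParams default used by the fixture


def test_root_negatives_respect_exclusion_radius(scene):
    cfg = root_config()
    tips = np.array([[a.x, a.y] for a in scene.annotations])
    for seed in range(10):
        negs = mine_negatives_root(scene, 12, cfg, np.random.default_rng(seed))
        for n in negs:
            x, y = n.source_xy
            d = np.hypot(tips[:, 0] - x, tips[:, 1] - y)
            assert d.min() > cfg.exclusion_radius


def test_on_root_mining_without_polylines_raises():
    raster = np.full((200, 200, 3), 230, np.uint8)
    img = AnnotatedImage("t", raster, [])
    with pytest.raises(ValueError, match="polylines"):
        mine_negatives_root(img, 4, root_config())


def test_shoot_negatives_on_blank_background_fall_back_to_random():
    raster = np.full((300, 300, 3), 240, np.uint8)
    img = AnnotatedImage("t", raster, [])
    negs = mine_negatives_shoot(img, 6, shoot_config(), np.random.default_rng(1))
    assert len(negs) == 6  # all random fallback; no Harris candidates


def test_harris_candidates_cluster_at_rectangle_corners():
    raster = np.zeros((200, 200, 3), np.uint8)
    raster[60:140, 50:150] = 255
    cand = harris_candidates(raster)
    corners = np.array([[50, 60], [149, 60], [50, 139], [149, 139]], float)
    assert len(cand) > 0
    # Every candidate is near a true corner, and every corner is found.
    d = np.hypot(cand[:, None, 0] - corners[None, :, 0],
                 cand[:, None, 1] - corners[None, :, 1])
    assert d.min(axis=1).max() <= 4.0
    assert d.min(axis=0).max() <= 4.0


def test_shoot_negative_centres_outside_exclusion_radius():
    cfg = shoot_config()
    for seed in range(10):
        img = generate_shoot_image(ShootSceneParams(seed=seed))
        pts = np.array([[a.x, a.y] for a in img.annotations])
        negs = mine_negatives_shoot(img, 20, cfg, np.random.default_rng(seed))
        for n in negs:
            x, y = n.source_xy
            assert np.hypot(pts[:, 0] - x, pts[:, 1] - y).min() > cfg.exclusion_radius


# --- split / mean / augmentation ---------------------------------------------

@pytest.mark.parametrize("n,expected_train", [
    (43641, 34912),   # root dataset cardinality
    (62118, 49694),   # shoot dataset cardinality
    (10, 8),
])
def test_split_cardinalities(n, expected_train):
    train, val = split_dataset(list(range(n)), root_config(rng_seed=5))
    assert len(train) == expected_train
    assert len(val) == n - expected_train


def test_split_is_a_reproducible_partition():
    items = list(range(503))
    cfg = root_config(rng_seed=9)
    t1, v1 = split_dataset(items, cfg)
    t2, v2 = split_dataset(items, cfg)
    assert t1 == t2 and v1 == v2
    assert set(t1) | set(v1) == set(items)
    assert set(t1) & set(v1) == set()


def _solid(value, side=42):
    patch = np.full((side, side, 3), 0, np.uint8)
    patch[:] = value
    return patchgen.PatchSample(patch, NEGATIVE_LABEL, "s", (0, 0))


def test_mean_color_solid_and_symmetric():
    assert compute_mean_color([_solid(100)]) == (100, 100, 100)
    assert compute_mean_color([_solid(0), _solid(200)]) == (100, 100, 100)


def test_mean_color_matches_flat_pixel_average():
    rng = np.random.default_rng(3)
    samples = [patchgen.PatchSample(
        rng.integers(0, 255, (42, 42, 3), dtype=np.uint8),
        NEGATIVE_LABEL, "s", (0, 0)) for _ in range(7)]
    mean = compute_mean_color(samples)
    stacked = np.concatenate([s.patch.reshape(-1, 3) for s in samples])
    expected = stacked.mean(axis=0)
    assert mean == pytest.approx(tuple(expected))


def test_root_augment_offsets_uniform_chi_square():
    cfg = root_config()
    rng = np.random.default_rng(12)
    base = np.zeros((42, 42, 3), np.uint8)
    # Encode the offset in the crop's corner pixel: pixel (y, x) value = y*42+x
    # is too big for uint8, so tag rows/cols separately.
    base[:, :, 0] = np.arange(42)[:, None]  # row index
    base[:, :, 1] = np.arange(42)[None, :]  # col index
    sample = patchgen.PatchSample(base, "root_tip", "s", (0, 0))
    counts = np.zeros((11, 11))
    n = 10_000
    for _ in range(n):
        crop = augment_for_training(sample, cfg, rng)
        oy, ox = int(crop[0, 0, 0]), int(crop[0, 0, 1])
        counts[oy, ox] += 1
    chi2 = ((counts - n / 121) ** 2 / (n / 121)).sum()
    # 120 dof; p > 0.001
    assert chi2 < stats.chi2.ppf(0.999, 120)


def test_root_augment_zero_offset_is_top_left_corner():
    cfg = root_config()
    rng = np.random.default_rng(0)
    patch = np.arange(42 * 42).reshape(42, 42) % 251
    patch = np.stack([patch] * 3, axis=-1).astype(np.uint8)
    sample = patchgen.PatchSample(patch, "root_tip", "s", (0, 0))
    # Draw until the (0, 0) offset appears, then check identity.
    for _ in range(2000):
        crop = augment_for_training(sample, cfg, rng)
        if np.array_equal(crop, patch[:32, :32]):
            break
    else:
        pytest.fail("offset (0,0) never produced the top-left sub-crop")


def test_shoot_downscale_preserves_constant():
    cfg = shoot_config()
    sample = _solid(137, side=128)
    out = augment_for_training(sample, cfg)
    assert out.shape == (64, 64, 3)
    assert np.all(out == 137)


def test_augment_rejects_wrong_input_side():
    cfg = root_config()
    with pytest.raises(ValueError):
        augment_for_training(_solid(1, side=32), cfg)


def test_build_dataset_negative_ratio_two_to_one(scene):
    cfg = root_config(rng_seed=2)
    train, val = patchgen.build_dataset([scene], cfg)
    labels = [s.label for s in train + val]
    n_pos = sum(l == "root_tip" for l in labels)
    n_neg = sum(l == NEGATIVE_LABEL for l in labels)
    assert n_neg == 2 * n_pos
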