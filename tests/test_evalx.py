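"""Accuracy metrics: published-count arithmetic and radius-based scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tipscan.evalx import (ConfusionCounts, classification_accuracy,
                           confusion_from_predictions,
                           feature_accuracy_from_rates, localization_metrics,
                           match_tips)
from tipscan.locmap import ClassMap

ROOT_COUNTS = ConfusionCounts({
    "root_tip": (2904, 73),
    "root_tip_negative": (5687, 65),
})

SHOOT_COUNTS = ConfusionCounts({
    "leaf_tip": (2225, 113),
    "leaf_base": (2299, 52),
    "ear_tip": (686, 15),
    "ear_base": (765, 23),
    "shoot_negative": (6110, 136),
})


def test_root_validation_accuracy_from_published_counts():
    assert classification_accuracy(ROOT_COUNTS) == 98.4
    assert classification_accuracy(ROOT_COUNTS, ["root_tip"]) == 97.5
    assert classification_accuracy(ROOT_COUNTS, ["root_tip_negative"]) == 98.9


def test_shoot_validation_accuracy_from_published_counts():
    assert classification_accuracy(SHOOT_COUNTS) == 97.3
    assert classification_accuracy(SHOOT_COUNTS, ["leaf_tip"]) == 95.2
    assert classification_accuracy(SHOOT_COUNTS, ["ear_tip"]) == 97.9
    assert classification_accuracy(SHOOT_COUNTS, ["ear_base"]) == 97.1


def test_perfect_class_gives_100():
    c = ConfusionCounts({"a": (50, 0)})
    assert classification_accuracy(c) == 100.0


def test_zero_samples_rejected():
    with pytest.raises(ValueError):
        classification_accuracy(ConfusionCounts({"a": (0, 0)}))


def test_confusion_from_predictions_counts():
    truth = np.array([0, 0, 1, 1, 1])
    pred = np.array([0, 1, 1, 1, 0])
    c = confusion_from_predictions(truth, pred, ["tip", "neg"])
    assert c.counts == {"tip": (1, 1), "neg": (2, 1)}


def _map(ny=20, nx=20, window=32, stride=4):
    grid = np.zeros((ny, nx, 2))
    return ClassMap(("root_tip", "negative"), grid, stride=stride, window=window)


def _disc_cells(cmap, truth, radius):
    centres = cmap.cell_centres()
    d2 = ((centres[:, None, :] - np.asarray(truth, float)[None]) ** 2).sum(axis=2)
    return d2.min(axis=1) <= radius ** 2


def test_perfect_detector_scores_100():
    cmap = _map()
    truth = np.array([[50.0, 50.0]])
    within = _disc_cells(cmap, truth, 16.0).reshape(20, 20)
    rep = localization_metrics(within, cmap, truth)
    assert rep.false_positive_pct == 0.0
    assert rep.false_negative_pct == 0.0
    assert rep.feature_accuracy_pct == 100.0


def test_no_predictions_fn_equals_disc_membership_count():
    cmap = _map()
    truth = np.array([[40.0, 60.0], [70.0, 30.0]])
    rep = localization_metrics(np.zeros((20, 20), bool), cmap, truth)
    expected_fn = _disc_cells(cmap, truth, 16.0).sum() / 400 * 100
    assert rep.false_negative_pct == pytest.approx(expected_fn)
    assert rep.false_positive_pct == 0.0


def test_single_far_positive_counting_oracle():
    cmap = _map()
    truth = np.array([[50.0, 50.0]])
    mask = np.zeros((20, 20), bool)
    mask[19, 19] = True  # cell centre (92, 92): far from truth
    rep = localization_metrics(mask, cmap, truth)
    disc = _disc_cells(cmap, truth, 16.0).sum()
    assert rep.false_positive_pct == pytest.approx(1 / 400 * 100)
    assert rep.false_negative_pct == pytest.approx(disc / 400 * 100)


def test_empty_truth_empty_mask_is_perfect():
    cmap = _map()
    rep = localization_metrics(np.zeros((20, 20), bool), cmap, np.empty((0, 2)))
    assert rep.feature_accuracy_pct == 100.0


@given(st.integers(0, 2 ** 31 - 1))
def test_accuracy_identity_holds_pre_rounding(seed):
    rng = np.random.default_rng(seed)
    cmap = _map()
    mask = rng.random((20, 20)) > 0.7
    truth = rng.uniform(0, 90, (3, 2))
    rep = localization_metrics(mask, cmap, truth)
    assert rep.feature_accuracy_pct + rep.false_positive_pct \
        + rep.false_negative_pct == pytest.approx(100.0, abs=1e-9)
    # Permutation invariance in truth ordering.
    rep2 = localization_metrics(mask, cmap, truth[::-1])
    assert rep2.false_positive_pct == rep.false_positive_pct
    assert rep2.false_negative_pct == rep.false_negative_pct


def test_adding_far_positive_cell_raises_fp_only():
    rng = np.random.default_rng(0)
    cmap = _map()
    truth = np.array([[50.0, 50.0]])
    mask = rng.random((20, 20)) > 0.8
    rep_before = localization_metrics(mask, cmap, truth)
    far = np.unravel_index(
        np.argmin(_disc_cells(cmap, truth, 16.0)
                  | mask.ravel()), mask.shape)
    mask2 = mask.copy()
    mask2[far] = True
    rep_after = localization_metrics(mask2, cmap, truth)
    assert rep_after.false_positive_pct >= rep_before.false_positive_pct
    assert rep_after.false_negative_pct == rep_before.false_negative_pct


def test_table_style_identity_from_rates():
    assert feature_accuracy_from_rates(0.03, 0.12) == pytest.approx(99.85)
    assert feature_accuracy_from_rates(0.24, 0.12) == pytest.approx(99.64)
    assert feature_accuracy_from_rates(0.22, 0.10) == pytest.approx(99.68)


def test_match_tips_recall_and_spurious():
    truth = np.array([[10.0, 10.0], [50.0, 50.0]])
    detected = np.array([[12.0, 11.0], [90.0, 90.0]])
    rec, spur = match_tips(detected, truth, radius=16.0)
    assert rec == 50.0   # one of two truths recovered
    assert spur == 50.0  # one spurious detection per two truths
    rec, spur = match_tips(np.empty((0, 2)), truth, 16.0)
    assert rec == 0.0 and spur == 0.0
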