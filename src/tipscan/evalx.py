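"""Classification and localization accuracy metrics.

Classification accuracy aggregates correct/misclassified counts over a
chosen subset of classes.  Localization accuracy scores a thresholded scan
map against ground-truth feature points using a radius of half the
classification window: a positive cell farther than the radius from every
truth point is a false positive; a non-positive cell within the radius of
some truth point is a false negative; everything else is correct.  Both
rates are percentages of all map cells and the identity

    feature_accuracy = 100 - FP% - FN%

holds exactly before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .locmap import ClassMap


@dataclass
class ConfusionCounts:
    """Per-class correct / misclassified validation counts."""

    counts: Mapping[str, tuple[int, int]]  # class -> (correct, misclassified)

    def __post_init__(self) -> None:
        for cls, (c, m) in self.counts.items():
            if c < 0 or m < 0:
                raise ValueError(f"{cls}: counts must be >= 0")


def classification_accuracy(counts: ConfusionCounts,
                            classes: Sequence[str] | None = None) -> float:
    """Percent correct over the selected classes, to one decimal place.

    ``100 * sum(correct) / sum(correct + misclassified)``; ``classes=None``
    aggregates every class (the "total/average" row).
    """
    if classes is None:
        classes = list(counts.counts)
    correct = sum(counts.counts[c][0] for c in classes)
    total = correct + sum(counts.counts[c][1] for c in classes)
    if total == 0:
        raise ValueError("classification_accuracy: zero samples")
    return round(100.0 * correct / total, 1)


def confusion_from_predictions(truth: np.ndarray, predicted: np.ndarray,
                               class_names: Sequence[str]) -> ConfusionCounts:
    """Build per-class correct/misclassified counts from label arrays."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    counts = {}
    for k, name in enumerate(class_names):
        sel = truth == k
        correct = int(np.sum(predicted[sel] == k))
        counts[name] = (correct, int(sel.sum()) - correct)
    return ConfusionCounts(counts)


@dataclass
class LocalizationReport:
    """Radius-based localization scores, in percent of all map cells."""

    false_positive_pct: float
    false_negative_pct: float
    feature_accuracy_pct: float
    radius: float
    n_cells: int


def localization_metrics(positive_mask: np.ndarray, cmap: ClassMap,
                         truth_points: np.ndarray,
                         radius: float | None = None) -> LocalizationReport:
    """Score a thresholded map against ground-truth points.

    ``positive_mask`` is the boolean grid (same shape as the map);
    ``truth_points`` an (n, 2) array of (x, y) image coordinates (may be
    empty); ``radius`` defaults to half the classification window.
    Distances are Euclidean in image pixels.
    """
    if radius is None:
        radius = cmap.window / 2.0
    positive_mask = np.asarray(positive_mask, bool)
    if positive_mask.shape != cmap.grid.shape[:2]:
        raise ValueError("mask shape does not match the map grid")
    truth_points = np.asarray(truth_points, float).reshape(-1, 2)
    centres = cmap.cell_centres()
    n_cells = len(centres)
    if len(truth_points) == 0:
        within = np.zeros(n_cells, bool)
    else:
        d2 = ((centres[:, None, :] - truth_points[None, :, :]) ** 2).sum(axis=2)
        within = (d2.min(axis=1) <= radius * radius)
    pos = positive_mask.ravel()
    fp = float(np.sum(pos & ~within)) / n_cells * 100.0
    fn = float(np.sum(~pos & within)) / n_cells * 100.0
    return LocalizationReport(
        false_positive_pct=fp,
        false_negative_pct=fn,
        feature_accuracy_pct=100.0 - fp - fn,
        radius=float(radius),
        n_cells=n_cells,
    )


def feature_accuracy_from_rates(fp_pct: float, fn_pct: float) -> float:
    """The Table-style identity: accuracy = 100 - FP% - FN%."""
    return 100.0 - fp_pct - fn_pct


def match_tips(detected: np.ndarray, truth: np.ndarray, radius: float
               ) -> tuple[float, float]:
    """Point-level detection scores: (recall %, spurious %, of truth count).

    A truth tip is recovered if some detection lies within ``radius``; a
    detection is spurious if no truth tip lies within ``radius``.  The
    spurious rate is expressed relative to the truth count, matching how
    over-detection is judged against ground truth.
    """
    detected = np.asarray(detected, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    if len(truth) == 0:
        # No truth: recall is vacuously perfect; any detection is spurious
        # but there is no truth count to normalise by.
        return 100.0, (0.0 if len(detected) == 0 else float("inf"))
    if len(detected) == 0:
        return 0.0, 0.0
    d2 = ((truth[:, None, :] - detected[None, :, :]) ** 2).sum(axis=2)
    recovered = np.sum(d2.min(axis=1) <= radius * radius)
    spurious = np.sum(d2.min(axis=0) > radius * radius)
    return (100.0 * recovered / len(truth), 100.0 * spurious / len(truth))
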