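"""From probability maps to discrete tip coordinates.

The thresholded map is cleaned by binary erosion with a full 3x3 structuring
element (3 iterations by default) to remove single-cell artefacts and split
touching tips; a connected-component pass (8-connectivity) then yields one
centroid per foreground region, mapped back to source-image pixels through
the map geometry.  Erosion operates on the stride-resolution grid — the
"heat map" is the scan output itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .locmap import ClassMap, threshold_map

_SE_3X3 = np.ones((3, 3), bool)


@dataclass
class TipSet:
    """Detected (or ground-truth) feature centroids in image pixels."""

    image_id: str
    tips: np.ndarray  # (n, 2) array of (x, y); may be empty
    source: str = "detector"

    def __post_init__(self) -> None:
        self.tips = np.asarray(self.tips, float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.tips)


def erode_mask(mask: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Binary erosion with the full 3x3 structuring element.

    A cell survives one iteration iff its entire 3x3 neighbourhood is
    foreground; outside the mask counts as background.  ``iterations=0``
    returns the mask unchanged.
    """
    mask = np.asarray(mask, bool)
    if iterations <= 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_SE_3X3,
                                  iterations=iterations, border_value=0)


def mask_centroids(mask: np.ndarray) -> np.ndarray:
    """Centroids (unweighted mean of member cells) of 8-connected regions.

    Returns an (n, 2) array of (col, row) grid coordinates.
    """
    labels, n = ndimage.label(mask, structure=_SE_3X3)
    if n == 0:
        return np.empty((0, 2), float)
    cys = ndimage.mean(np.indices(mask.shape)[0], labels, np.arange(1, n + 1))
    cxs = ndimage.mean(np.indices(mask.shape)[1], labels, np.arange(1, n + 1))
    return np.stack([cxs, cys], axis=1)


def extract_tips(cmap: ClassMap, feature_class: str = "root_tip",
                 threshold: float = 0.5, iterations: int = 3) -> TipSet:
    """Threshold → erode → label → centroid → image coordinates.

    An empty result is valid (no foreground survives erosion).
    """
    mask = threshold_map(cmap, feature_class, threshold)
    eroded = erode_mask(mask, iterations)
    cent = mask_centroids(eroded)
    if len(cent) == 0:
        return TipSet(cmap.image_id, np.empty((0, 2)), source="detector")
    xs, ys = cmap.cell_to_image(cent[:, 1], cent[:, 0])
    return TipSet(cmap.image_id, np.stack([xs, ys], axis=1), source="detector")


def write_tips_csv(tipsets, path: str | Path) -> Path:
    """Export tip coordinates as CSV rows of (image_id, x, y)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for ts in tipsets:
            for x, y in ts.tips:
                writer.writerow([ts.image_id, repr(float(x)), repr(float(y))])
    return path


def read_tips_csv(path: str | Path) -> list[TipSet]:
    """Read a tips CSV back into one TipSet per image_id (file order)."""
    groups: dict[str, list] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            groups.setdefault(row["image_id"], []).append(
                (float(row["x"]), float(row["y"]))
            )
    return [TipSet(k, np.asarray(v), source="csv") for k, v in groups.items()]
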