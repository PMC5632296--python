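"""Sliding-window scanning: turn a patch classifier into probability maps.

The classifier is applied at every window position on a regular stride grid
(default stride 4 px).  Windows are fully interior — no border padding — so
the resulting map is smaller than the image and cell ``(i, j)`` corresponds
to the window centred at ``(window/2 + j*stride, window/2 + i*stride)`` in
image coordinates.  That grid-to-image mapping is exactly invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .net import TrainedModel


@dataclass
class ClassMap:
    """Per-class probability grid with its scan geometry."""

    class_names: tuple[str, ...]
    grid: np.ndarray  # ny x nx x n_classes
    stride: int
    window: int
    image_id: str = ""

    @property
    def origin(self) -> tuple[float, float]:
        """Image coordinates (x0, y0) of grid cell (0, 0) — the first
        window's centre."""
        return self.window / 2.0, self.window / 2.0

    def cell_to_image(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        """Map grid indices (row i, column j) to image (x, y)."""
        x0, y0 = self.origin
        return x0 + self.stride * np.asarray(j), y0 + self.stride * np.asarray(i)

    def image_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`cell_to_image` (exact on grid points)."""
        x0, y0 = self.origin
        return (np.asarray(y) - y0) / self.stride, (np.asarray(x) - x0) / self.stride

    def cell_centres(self) -> np.ndarray:
        """All cell positions in image coordinates, shape (ny*nx, 2) of (x, y)."""
        ny, nx = self.grid.shape[:2]
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        xs, ys = self.cell_to_image(ii.ravel(), jj.ravel())
        return np.stack([xs, ys], axis=1)


def scan_image(model: TrainedModel, image: np.ndarray, stride: int = 4,
               batch_size: int = 1024, image_id: str = "") -> ClassMap:
    """Classify every stride-spaced window of ``image``; return the map.

    ``image`` is H x W x 3 (uint8).  The grid has
    ``floor((W-window)/stride)+1`` columns and the analogous row count.
    Batched evaluation is used but is numerically identical to classifying
    one window at a time.
    """
    window = model.spec.input_side
    h, w = image.shape[:2]
    if h < window or w < window:
        raise ValueError(f"image {w}x{h} smaller than window {window}")
    windows = sliding_window_view(image, (window, window), axis=(0, 1))
    windows = windows[::stride, ::stride]  # ny x nx x 3 x win x win
    ny, nx = windows.shape[:2]
    flat = np.ascontiguousarray(
        windows.transpose(0, 1, 3, 4, 2).reshape(ny * nx, window, window, 3)
    )
    probs = model.predict_proba(flat, batch_size=batch_size)
    grid = probs.reshape(ny, nx, -1)
    return ClassMap(class_names=model.class_names, grid=grid, stride=stride,
                    window=window, image_id=image_id)


def threshold_map(cmap: ClassMap, feature_class: str, threshold: float = 0.5
                  ) -> np.ndarray:
    """Boolean mask on the map grid: probability of ``feature_class`` >
    ``threshold``."""
    if feature_class not in cmap.class_names:
        raise KeyError(
            f"unknown class {feature_class!r}; map has {cmap.class_names}"
        )
    k = cmap.class_names.index(feature_class)
    return cmap.grid[..., k] > threshold


def save_class_map(cmap: ClassMap, path: str | Path) -> Path:
    """Serialize the probability grid (.npz) plus a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), grid=cmap.grid)
    sidecar = {
        "class_names": list(cmap.class_names),
        "stride": cmap.stride,
        "window": cmap.window,
        "image_id": cmap.image_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_class_map(path: str | Path) -> ClassMap:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as npz:
        grid = npz["grid"]
    return ClassMap(class_names=tuple(sidecar["class_names"]), grid=grid,
                    stride=int(sidecar["stride"]), window=int(sidecar["window"]),
                    image_id=sidecar.get("image_id", ""))


def render_overlay(image: np.ndarray, cmap: ClassMap, feature_class: str,
                   threshold: float = 0.5,
                   colour: tuple[int, int, int] = (255, 200, 0)) -> np.ndarray:
    """Visualization utility: tint above-threshold cells onto a copy of the
    image (heat-map style overlay).  Not intended to be bit-exact."""
    out = image.copy()
    mask = threshold_map(cmap, feature_class, threshold)
    half = cmap.stride // 2 + 1
    for i, j in zip(*np.nonzero(mask)):
        x, y = cmap.cell_to_image(i, j)
        x, y = int(x), int(y)
        y0, y1 = max(y - half, 0), min(y + half + 1, out.shape[0])
        x0, x1 = max(x - half, 0), min(x + half + 1, out.shape[1])
        out[y0:y1, x0:x1] = (0.4 * out[y0:y1, x0:x1]
                             + 0.6 * np.array(colour)).astype(np.uint8)
    return out
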