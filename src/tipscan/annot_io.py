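"""Annotated-image and trait-table I/O.

The on-disk formats are deliberately simple and text-first:

* a dataset *manifest* is one JSON file holding, per image, the raster path
  (relative to the manifest), point annotations, optional root polylines and an
  optional recorded seed position;
* a flat CSV is accepted for annotation-only import;
* the trait table is a CSV with one row per image and a fixed, documented
  column order;
* RSML (Root System Markup Language) files can be read, tolerantly, to obtain
  root polylines; the tip of each root is taken as the last polyline point.

Rasters are 8-bit RGB PNG/JPEG read and written through Pillow.
"""

from __future__ import annotations

import csv
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

#: Closed vocabulary of point-feature classes.
FEATURE_CLASSES = ("root_tip", "leaf_tip", "leaf_base", "ear_tip", "ear_base")

#: Column order of the exported trait table (after the leading ``image_id``).
TRAIT_COLUMNS = (
    "tip_count",
    "hull_area",
    "width",
    "depth",
    "width_depth_ratio",
    "mean_x",
    "mean_y",
    "sd_x",
    "sd_y",
    "top100_count",
    "top200_count",
    "top300_count",
    "total_length",
    "centre_mass_x",
    "centre_mass_y",
    "seed_x",
    "seed_y",
)


class ManifestError(ValueError):
    """Raised for malformed or inconsistent manifests / annotation tables."""


@dataclass
class PointAnnotation:
    """A single point feature: class label plus pixel coordinates.

    ``root_length`` optionally records the arc length (pixels) of the root
    bearing a tip; it is used to filter out very short laterals that would be
    ambiguous with root hairs.
    """

    feature_class: str
    x: float
    y: float
    root_length: float | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ManifestError(
                f"unknown feature class {self.feature_class!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )
        if self.root_length is not None and self.root_length < 0:
            raise ManifestError("root_length must be >= 0 when present")


@dataclass
class AnnotatedImage:
    """An 8-bit RGB raster with point annotations and optional polylines.

    Coordinates are x-rightward, y-downward, 0-based, pixel centres.
    """

    image_id: str
    raster: np.ndarray  # H x W x 3 uint8
    annotations: list[PointAnnotation] = field(default_factory=list)
    polylines: list[np.ndarray] | None = None  # each (n, 2) float array of (x, y)
    seed_position: tuple[float, float] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the raster."""
        return self.raster.shape[0], self.raster.shape[1]

    def validate(self) -> None:
        h, w = self.shape
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise ManifestError(f"{self.image_id}: raster must be H x W x 3")
        for a in self.annotations:
            if not (0 <= a.x < w and 0 <= a.y < h):
                raise ManifestError(
                    f"{self.image_id}: annotation ({a.x}, {a.y}) outside "
                    f"[0, {w}) x [0, {h})"
                )


def _annotation_to_dict(a: PointAnnotation) -> dict:
    d = {"feature_class": a.feature_class, "x": a.x, "y": a.y}
    if a.root_length is not None:
        d["root_length"] = a.root_length
    return d


def write_manifest(images: Sequence[AnnotatedImage], directory: str | Path,
                   manifest_name: str = "manifest.json") -> Path:
    """Write rasters as PNG plus a JSON manifest into ``directory``.

    Returns the manifest path.  Image ids must be unique; each raster is saved
    as ``<image_id>.png`` next to the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [im.image_id for im in images]
    if len(set(ids)) != len(ids):
        raise ManifestError("image_id values must be unique within a manifest")
    records = []
    for im in images:
        im.validate()
        png_name = f"{im.image_id}.png"
        Image.fromarray(im.raster).save(directory / png_name)
        rec = {
            "image_id": im.image_id,
            "path": png_name,
            "annotations": [_annotation_to_dict(a) for a in im.annotations],
        }
        if im.polylines is not None:
            rec["polylines"] = [np.asarray(p, float).tolist() for p in im.polylines]
        if im.seed_position is not None:
            rec["seed_position"] = list(im.seed_position)
        records.append(rec)
    manifest_path = directory / manifest_name
    manifest_path.write_text(json.dumps({"images": records}, indent=1))
    return manifest_path


def read_manifest(path: str | Path) -> list[AnnotatedImage]:
    """Read a JSON manifest and load every referenced raster.

    Raises :class:`ManifestError` naming the missing image path or the
    offending record when a raster is absent or a feature class is unknown.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ManifestError(f"{path}: not valid JSON ({e})") from e
    images: list[AnnotatedImage] = []
    for i, rec in enumerate(doc.get("images", [])):
        img_path = path.parent / rec["path"]
        if not img_path.exists():
            raise ManifestError(
                f"{path} record {i} ({rec.get('image_id', '?')}): "
                f"image file not found: {img_path}"
            )
        raster = np.asarray(Image.open(img_path).convert("RGB"))
        anns = [
            PointAnnotation(
                feature_class=a["feature_class"],
                x=float(a["x"]),
                y=float(a["y"]),
                root_length=(
                    float(a["root_length"]) if a.get("root_length") is not None else None
                ),
            )
            for a in rec.get("annotations", [])
        ]
        polylines = None
        if "polylines" in rec:
            polylines = [np.asarray(p, float) for p in rec["polylines"]]
        seed = tuple(rec["seed_position"]) if rec.get("seed_position") else None
        im = AnnotatedImage(
            image_id=rec["image_id"],
            raster=raster,
            annotations=anns,
            polylines=polylines,
            seed_position=seed,
        )
        im.validate()
        images.append(im)
    ids = [im.image_id for im in images]
    if len(set(ids)) != len(ids):
        raise ManifestError(f"{path}: duplicate image_id values")
    return images


def read_annotations_csv(path: str | Path) -> dict[str, list[PointAnnotation]]:
    """Read an annotation-only CSV into ``{image_id: [PointAnnotation, ...]}``.

    Expected columns: ``image_id, feature_class, x, y[, root_length]``.
    Malformed rows raise :class:`ManifestError` with the 1-based line number.
    """
    path = Path(path)
    out: dict[str, list[PointAnnotation]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                length = row.get("root_length")
                ann = PointAnnotation(
                    feature_class=row["feature_class"].strip(),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    root_length=float(length) if length not in (None, "", "NA") else None,
                )
            except (KeyError, ValueError, ManifestError) as e:
                raise ManifestError(f"{path} line {lineno}: {e}") from e
            out.setdefault(row["image_id"].strip(), []).append(ann)
    return out


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float) and math.isnan(v):
        return "NA"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_trait_table(records, path: str | Path) -> Path:
    """Write root-trait vectors to CSV, one row per image.

    ``records`` is a non-empty sequence of :class:`tipscan.traits.TraitVector`.
    Missing values (e.g. an undefined width:depth ratio) are written as ``NA``.
    Numeric formatting uses ``repr`` and is locale independent.
    """
    records = list(records)
    if not records:
        raise ValueError("write_trait_table: records must be non-empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("image_id",) + TRAIT_COLUMNS)
        for r in records:
            writer.writerow([r.image_id] + [_fmt(getattr(r, c)) for c in TRAIT_COLUMNS])
    return path


def read_trait_table(path: str | Path) -> list[dict]:
    """Read a trait CSV back into dicts; ``NA`` becomes ``float('nan')``."""
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            rec: dict = {"image_id": row["image_id"]}
            for c in TRAIT_COLUMNS:
                v = row[c]
                rec[c] = float("nan") if v == "NA" else float(v)
            out.append(rec)
    return out


def read_rsml(path: str | Path) -> tuple[list[np.ndarray], list[PointAnnotation]]:
    """Tolerantly read root polylines from an RSML file.

    Returns ``(polylines, tip_annotations)`` where each tip is the last point
    of one root polyline (class ``root_tip``, ``root_length`` = arc length).
    Any ``<root>`` without usable geometry is silently skipped; a missing file
    is the caller's concern (use ``Path.exists`` first if absence is allowed).
    """
    tree = ET.parse(str(path))
    polylines: list[np.ndarray] = []
    tips: list[PointAnnotation] = []
    for root_el in tree.iter():
        if root_el.tag.rsplit("}", 1)[-1] != "root":
            continue
        # Geometry is taken from the root's own <geometry> child so that
        # nested lateral <root> elements are not double-counted.
        geom = next(
            (c for c in list(root_el) if c.tag.rsplit("}", 1)[-1] == "geometry"), None
        )
        if geom is None:
            continue
        pts = []
        for pt in geom.iter():
            if pt.tag.rsplit("}", 1)[-1] != "point":
                continue
            try:
                pts.append((float(pt.get("x")), float(pt.get("y"))))
            except (TypeError, ValueError):
                continue
        if len(pts) < 2:
            continue
        poly = np.asarray(pts, float)
        polylines.append(poly)
        arc = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
        tips.append(
            PointAnnotation("root_tip", x=poly[-1, 0], y=poly[-1, 1], root_length=arc)
        )
    return polylines, tips
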