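"""Image and manifest I/O.

Canonical pixel form for the whole pipeline: a 2-D float array of
fluorescence intensities in [0, 1]. RGB images are reduced to the green
channel, where FITC emission lives; integer images are scaled by their
bit-depth maximum.

Dataset manifests group images into wells and carry ground-truth labels at
the well, image and (optionally) cell level. Two dialects are supported:

* CSV, header ``well_id,image_path,magnification_scale,image_label,well_label``
  (flat, no cell annotations);
* JSON, ``{"images": [{"well_id", "image_path", "magnification_scale",
  "image_label", "well_label", "cells": [{"x", "y", "label"}]}]}``.

Coordinates are 0-based ``(x=column, y=row)`` with pixel centers at integers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

POSITIVE = "positive"
NEGATIVE = "negative"
SUSPENDED = "suspended"

_LABEL_TOKENS = {POSITIVE, NEGATIVE}

MIN_IMAGE_SIDE = 64


class ManifestError(ValueError):
    """A dataset manifest violates its schema or invariants."""


def parse_label(token: str | None) -> str | None:
    """Parse a class label case-insensitively; ``None``/empty stays ``None``."""
    if token is None:
        return None
    token = token.strip()
    if not token:
        return None
    low = token.lower()
    if low not in _LABEL_TOKENS:
        raise ManifestError(
            f"unrecognized label {token!r}; accepted tokens (case-insensitive): "
            f"{sorted(_LABEL_TOKENS)}"
        )
    return low


@dataclass
class WellImage:
    """One acquired field of a well in canonical form."""

    well_id: str
    image_id: str
    pixels: np.ndarray  # 2-D float64, intensities in [0, 1]
    magnification_scale: float  # 1.0 = reference 50-fold scale, 0.5 = 25-fold
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D intensity grid")
        h, w = self.pixels.shape
        if w < MIN_IMAGE_SIDE or h < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {self.image_id!r} is {w}x{h}; minimum side is {MIN_IMAGE_SIDE}"
            )
        if self.magnification_scale <= 0:
            raise ValueError("magnification_scale must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities outside [0, 1]: min={lo}, max={hi}")
        if self.true_label is not None:
            self.true_label = parse_label(self.true_label)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class CellAnnotation:
    """Specialist label for a single cell, placed at its centroid."""

    x: float
    y: float
    label: str


@dataclass
class ManifestRecord:
    well_id: str
    image_path: str
    magnification_scale: float = 1.0
    image_label: str | None = None
    well_label: str | None = None
    cells: tuple[CellAnnotation, ...] = field(default_factory=tuple)

    @property
    def image_id(self) -> str:
        return Path(self.image_path).stem


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    root: Path | None = None  # directory image paths are relative to

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            dup = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestError(f"duplicate image paths in manifest: {dup}")
        for r in self.records:
            if not r.well_id:
                raise ManifestError(f"record {r.image_path!r} has empty well_id")
        for well_id, recs in self.wells().items():
            labels = {r.well_label for r in recs if r.well_label is not None}
            if len(labels) > 1:
                raise ManifestError(
                    f"well {well_id!r} carries conflicting well labels {sorted(labels)}"
                )
            if labels:
                (well_label,) = labels
                img_labels = {r.image_label for r in recs if r.image_label is not None}
                if img_labels - {well_label}:
                    raise ManifestError(
                        f"well {well_id!r}: image labels {sorted(img_labels)} conflict "
                        f"with well label {well_label!r}"
                    )

    def wells(self) -> dict[str, list[ManifestRecord]]:
        """Records grouped by well, insertion order preserved."""
        groups: dict[str, list[ManifestRecord]] = {}
        for r in self.records:
            groups.setdefault(r.well_id, []).append(r)
        return groups

    def resolve(self, record: ManifestRecord) -> Path:
        p = Path(record.image_path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


def canonicalize_pixels(raw: np.ndarray) -> np.ndarray:
    """Reduce a decoded image array to the canonical [0, 1] grayscale form.

    Idempotent: a float 2-D array already in [0, 1] is returned unchanged
    (up to dtype). RGB(A) arrays keep only the green channel; integer dtypes
    are divided by their type maximum.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("zero-sized image")
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, 1]  # green channel: FITC emission
    elif arr.ndim != 2:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale
    out = arr.astype(np.float64)
    if out.size and (out.min() < 0.0 or out.max() > 1.0):
        raise ValueError("float image must already be scaled to [0, 1]")
    return out


def load_image(
    path: str | Path,
    magnification_scale: float,
    well_id: str = "",
    image_id: str | None = None,
    true_label: str | None = None,
) -> WellImage:
    """Load one well image from disk into canonical form."""
    import imageio.v3 as iio

    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by backend
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    pixels = canonicalize_pixels(raw)
    return WellImage(
        well_id=well_id or path.stem,
        image_id=image_id if image_id is not None else path.stem,
        pixels=pixels,
        magnification_scale=magnification_scale,
        true_label=true_label,
    )


def load_record(manifest: DatasetManifest, record: ManifestRecord) -> WellImage:
    """Load the image a manifest record points at, carrying its labels."""
    label = record.image_label or record.well_label
    img = load_image(
        manifest.resolve(record),
        record.magnification_scale,
        well_id=record.well_id,
        image_id=record.image_id,
        true_label=label,
    )
    for ann in record.cells:
        if not (0 <= ann.x < img.width and 0 <= ann.y < img.height):
            raise ManifestError(
                f"cell annotation ({ann.x}, {ann.y}) outside image "
                f"{record.image_path!r} bounds {img.width}x{img.height}"
            )
    return img


def _record_from_json(obj: dict) -> ManifestRecord:
    cells = tuple(
        CellAnnotation(float(c["x"]), float(c["y"]), parse_label(c["label"]))
        for c in obj.get("cells", [])
    )
    return ManifestRecord(
        well_id=str(obj["well_id"]),
        image_path=str(obj["image_path"]),
        magnification_scale=float(obj.get("magnification_scale", 1.0)),
        image_label=parse_label(obj.get("image_label")),
        well_label=parse_label(obj.get("well_label")),
        cells=cells,
    )


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest (CSV or JSON, chosen by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        records = [_record_from_json(o) for o in doc["images"]]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"well_id", "image_path"}
            if reader.fieldnames is None or required - set(reader.fieldnames):
                raise ManifestError(
                    f"manifest CSV must carry at least columns {sorted(required)}"
                )
            records = [
                ManifestRecord(
                    well_id=row["well_id"],
                    image_path=row["image_path"],
                    magnification_scale=float(row.get("magnification_scale") or 1.0),
                    image_label=parse_label(row.get("image_label")),
                    well_label=parse_label(row.get("well_label")),
                )
                for row in reader
            ]
    return DatasetManifest(records=records, root=path.parent)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest in the dialect matching the file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "images": [
                {
                    "well_id": r.well_id,
                    "image_path": r.image_path,
                    "magnification_scale": r.magnification_scale,
                    "image_label": r.image_label,
                    "well_label": r.well_label,
                    "cells": [
                        {"x": c.x, "y": c.y, "label": c.label} for c in r.cells
                    ],
                }
                for r in manifest.records
            ]
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["well_id", "image_path", "magnification_scale", "image_label", "well_label"]
            )
            for r in manifest.records:
                writer.writerow(
                    [
                        r.well_id,
                        r.image_path,
                        r.magnification_scale,
                        r.image_label or "",
                        r.well_label or "",
                    ]
                )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as the reported percentages are."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def dataset_summary(manifest: DatasetManifest, level: str = "images") -> dict:
    """Counts and class percentages at one level: wells, images or cells.

    Percentages are computed from exact integer counts and rounded half-up
    to one decimal.
    """
    if level == "wells":
        labels = []
        for well_id, recs in manifest.wells().items():
            lab = {r.well_label for r in recs if r.well_label is not None}
            if not lab:
                raise ManifestError(f"well {well_id!r} has no well label")
            labels.append(lab.pop())
    elif level == "images":
        labels = [r.image_label or r.well_label for r in manifest.records]
        if any(lab is None for lab in labels):
            raise ManifestError("some images have no image or well label")
    elif level == "cells":
        labels = [c.label for r in manifest.records for c in r.cells]
        if not labels:
            raise ManifestError("manifest carries no cell annotations")
    else:
        raise ValueError(f"unknown level {level!r}")

    n = len(labels)
    n_pos = sum(1 for lab in labels if lab == POSITIVE)
    n_neg = n - n_pos
    return {
        "level": level,
        "n": n,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": round_half_up(100.0 * n_pos / n) if n else 0.0,
        "pct_negative": round_half_up(100.0 * n_neg / n) if n else 0.0,
    }


def relabel(record: ManifestRecord, **changes) -> ManifestRecord:
    return replace(record, **changes)
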