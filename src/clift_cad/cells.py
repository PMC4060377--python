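"""Cell localization and scale-normalized cropping.

Each candidate kinetoplast region anchors a search for its host cell: a
window of three expected cell lengths is taken around the candidate, the
cell body is segmented inside it (Otsu threshold on the median-subtracted
window, then morphological closing), and the connected body component
containing — or within 5 px of — the candidate is kept. Candidates farther
than that from any body are extracellular artifacts and are discarded:
a kinetoplast is an organelle and cannot lie outside a cell.

A body claimed by several candidates produces ONE crop holding all of them,
so a multi-spot cell is judged once. Every crop is resampled so the body
major axis is ~64 px; all downstream texture parameters are therefore
magnification-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .io import WellImage
from .screening import CandidateRegion, region_from_coords

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)

NORMALIZED_MAJOR_AXIS = 64.0  # px, body major axis after resampling
MIN_BODY_AREA = 50  # px, after normalization
MAX_CANDIDATE_BODY_DIST = 5.0  # px, beyond which a candidate is an artifact
EXPECTED_CELL_LENGTH = 40.0  # px at magnification scale 1.0
MIN_BODY_AXIS_FRAC = 0.4  # min body major axis, fraction of expected length
MAX_BODY_AXIS_FRAC = 2.0  # max body major axis, fraction of expected length


@dataclass
class CellCrop:
    """One localized cell, resampled to a common physical scale."""

    well_id: str
    image_id: str
    crop: np.ndarray  # 2-D intensities in [0, 1]
    body_mask: np.ndarray  # bool, same shape as crop
    candidates_in_cell: list[CandidateRegion]  # crop coordinates
    cell_centroid: tuple[float, float]  # (x, y) in image coordinates
    major_axis_len: float  # px, in image coordinates
    orientation: float  # radians
    true_label: str | None = None
    body_coords_image: np.ndarray = field(default=None, repr=False)  # (n,2) (row,col)

    def __post_init__(self) -> None:
        if not self.candidates_in_cell:
            raise ValueError("a CellCrop must contain at least one candidate region")
        if int(self.body_mask.sum()) < MIN_BODY_AREA:
            raise ValueError("body mask too small after normalization")


def _segment_body(
    window: np.ndarray, anchor_rc: tuple[float, float]
) -> np.ndarray | None:
    """Segment the cell body in a window; return the component mask for the
    anchor point, or None when the anchor is too far from any body."""
    corrected = np.clip(window - np.median(window), 0.0, None)
    if corrected.max() <= 0:
        return None
    # windows are tri-modal (background, cytoplasm, bright organelle); plain
    # Otsu can split cytoplasm from the spot instead of from background, so
    # take the lowest boundary of a 3-class split when it exists
    try:
        t = float(threshold_multiotsu(corrected, classes=3)[0])
    except ValueError:
        try:
            t = float(threshold_otsu(corrected))
        except ValueError:  # constant window
            return None
    mask = ndimage.binary_closing(corrected > t, structure=disk(2))
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return None
    r0 = int(round(anchor_rc[0]))
    c0 = int(round(anchor_rc[1]))
    r0 = np.clip(r0, 0, window.shape[0] - 1)
    c0 = np.clip(c0, 0, window.shape[1] - 1)
    lab = labels[r0, c0]
    if lab == 0:
        # nearest component within the tolerance
        rows, cols = np.nonzero(mask)
        d2 = (rows - anchor_rc[0]) ** 2 + (cols - anchor_rc[1]) ** 2
        idx = int(np.argmin(d2))
        if d2[idx] > MAX_CANDIDATE_BODY_DIST**2:
            return None
        lab = labels[rows[idx], cols[idx]]
    return labels == lab


def extract_cells(
    image: WellImage, candidates: list[CandidateRegion]
) -> list[CellCrop]:
    """Locate the host cell of each candidate and build normalized crops.

    An image may legally yield zero cells (every candidate extracellular).
    """
    h, w = image.pixels.shape
    window_side = int(round(3 * EXPECTED_CELL_LENGTH * image.magnification_scale))
    claimed: list[dict] = []  # bodies already segmented, image coords

    for cand in candidates:
        cx, cy = cand.centroid
        # a previously claimed body may already own this candidate
        owner = None
        for body in claimed:
            r0 = int(round(cy)) - body["r_off"]
            c0 = int(round(cx)) - body["c_off"]
            if (
                0 <= r0 < body["mask"].shape[0]
                and 0 <= c0 < body["mask"].shape[1]
                and body["mask"][r0, c0]
            ):
                owner = body
                break
        if owner is not None:
            owner["candidates"].append(cand)
            continue

        half = window_side // 2
        r_lo = max(0, int(round(cy)) - half)
        r_hi = min(h, int(round(cy)) + half + 1)
        c_lo = max(0, int(round(cx)) - half)
        c_hi = min(w, int(round(cx)) + half + 1)
        window = image.pixels[r_lo:r_hi, c_lo:c_hi]
        body = _segment_body(window, (cy - r_lo, cx - c_lo))
        if body is not None:
            # a genuine cell body is comparable to the expected cell length;
            # a bright artifact speckle segments into its own tiny blob, and
            # segmentation of a cell-free window yields a sprawling noise
            # blob — both are rejected by the axis gate
            props = regionprops(body.astype(np.uint8))[0]
            expected = EXPECTED_CELL_LENGTH * image.magnification_scale
            axis = props.axis_major_length
            if not (
                MIN_BODY_AXIS_FRAC * expected <= axis <= MAX_BODY_AXIS_FRAC * expected
            ):
                body = None
        if body is None:
            logger.debug(
                "candidate at (%.1f, %.1f) in %s discarded as extracellular artifact",
                cx, cy, image.image_id,
            )
            continue
        claimed.append(
            {"mask": body, "r_off": r_lo, "c_off": c_lo, "candidates": [cand]}
        )

    crops: list[CellCrop] = []
    for body in claimed:
        crop = _build_crop(image, body)
        if crop is not None:
            crops.append(crop)
    return crops


def _build_crop(image: WellImage, body: dict) -> CellCrop | None:
    mask = body["mask"]
    r_off, c_off = body["r_off"], body["c_off"]
    props = regionprops(mask.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    if major < 4.0:
        return None
    zoom = NORMALIZED_MAJOR_AXIS / major

    # tight bbox with margin, in window coordinates
    rows, cols = np.nonzero(mask)
    m = 6
    r_lo = max(0, rows.min() - m)
    r_hi = min(mask.shape[0], rows.max() + 1 + m)
    c_lo = max(0, cols.min() - m)
    c_hi = min(mask.shape[1], cols.max() + 1 + m)

    window = image.pixels[r_off + r_lo : r_off + r_hi, c_off + c_lo : c_off + c_hi]
    sub_mask = mask[r_lo:r_hi, c_lo:c_hi]

    crop = ndimage.zoom(window, zoom, order=1)
    crop = np.clip(crop, 0.0, 1.0)
    body_mask = ndimage.zoom(sub_mask.astype(np.uint8), zoom, order=0).astype(bool)
    # zoom may produce off-by-one shapes between the two arrays
    hh = min(crop.shape[0], body_mask.shape[0])
    ww = min(crop.shape[1], body_mask.shape[1])
    crop, body_mask = crop[:hh, :ww], body_mask[:hh, :ww]
    if int(body_mask.sum()) < MIN_BODY_AREA:
        return None

    # transplant candidate regions into crop coordinates
    cand_mask = np.zeros_like(sub_mask)
    for cand in body["candidates"]:
        rr = cand.coords[:, 0] - r_off - r_lo
        cc = cand.coords[:, 1] - c_off - c_lo
        keep = (rr >= 0) & (rr < cand_mask.shape[0]) & (cc >= 0) & (cc < cand_mask.shape[1])
        cand_mask[rr[keep], cc[keep]] = True
    cand_mask_z = ndimage.zoom(cand_mask.astype(np.uint8), zoom, order=0).astype(bool)
    cand_mask_z = cand_mask_z[:hh, :ww]
    labels, n = ndimage.label(cand_mask_z, structure=_EIGHT)
    crop_cands = []
    for lab in range(1, n + 1):
        coords = np.column_stack(np.nonzero(labels == lab))
        crop_cands.append(region_from_coords(coords, crop))
    if not crop_cands:
        return None
    crop_cands.sort(key=lambda r: (-r.max_intensity, r.centroid[1], r.centroid[0]))

    cy, cx = props.centroid  # window coordinates (row, col)
    return CellCrop(
        well_id=image.well_id,
        image_id=image.image_id,
        crop=crop,
        body_mask=body_mask,
        candidates_in_cell=crop_cands,
        cell_centroid=(cx + c_off, cy + r_off),
        major_axis_len=major,
        orientation=float(props.orientation),
        body_coords_image=np.column_stack(
            [np.nonzero(mask)[0] + r_off, np.nonzero(mask)[1] + c_off]
        ),
    )


def match_annotations(cells: list[CellCrop], annotations) -> int:
    """Assign specialist labels to crops by centroid-in-body matching.

    Each annotation labels at most one crop: the one whose body contains its
    centroid, nearest body centroid winning on overlap. Returns the number
    of annotations that matched no crop (each is logged as a warning).
    """
    unmatched = 0
    # pre-build per-crop membership sets
    coord_sets = [
        {(int(r), int(c)) for r, c in crop.body_coords_image} for crop in cells
    ]
    for ann in annotations:
        pt = (int(round(ann.y)), int(round(ann.x)))
        hits = [i for i, cs in enumerate(coord_sets) if pt in cs]
        if not hits:
            unmatched += 1
            logger.warning(
                "annotation at (%.1f, %.1f) matched no segmented cell body", ann.x, ann.y
            )
            continue
        if len(hits) > 1:
            hits.sort(
                key=lambda i: (
                    (cells[i].cell_centroid[0] - ann.x) ** 2
                    + (cells[i].cell_centroid[1] - ann.y) ** 2,
                    cells[i].cell_centroid[1],
                    cells[i].cell_centroid[0],
                )
            )
            logger.warning(
                "annotation at (%.1f, %.1f) inside %d overlapping bodies; "
                "assigned to nearest centroid",
                ann.x, ann.y, len(hits),
            )
        cells[hits[0]].true_label = ann.label
    return unmatched
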