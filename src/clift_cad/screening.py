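"""Step 1: threshold-based detection of candidate kinetoplast regions.

A kinetoplast appears as a compact set of pixels clearly more fluorescent
than the rest of the field. Detection therefore works on a background- and
pedestal-corrected image: the per-image median (ambient background) is
subtracted, then large-scale structure — the cell-body cytoplasm pedestal
and the broad nucleus blob — is suppressed by subtracting a Gaussian-blurred
version of the image (blur scale twice the nominal kinetoplast radius).
What survives is thresholded at ``mu + k_sigma * sigma`` of the corrected
intensities, so the threshold adapts per image to exposure and noise.
Connected components (8-connectivity) are then gated by area, expressed in
scale-normalized units of the nominal kinetoplast area ``pi * (2.5 *
magnification_scale)**2``, and by compactness ``4*pi*A/P**2``, which rejects
elongated streaks and retains round spots.

An image with no surviving candidate is pre-screened as negative and never
reaches the cell classifier; an image with candidates is only *presumed*
positive — the cell classifier decides whether the spots are true
kinetoplasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _perimeter

from .io import WellImage

NOMINAL_KINETOPLAST_SIGMA = 2.5  # px at magnification scale 1.0

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ScreeningParams:
    """Free parameters of the threshold-based screening step."""

    k_sigma: float = 4.0
    min_area_scale: float = 0.25  # in units of nominal kinetoplast area
    max_area_scale: float = 6.0
    min_compactness: float = 0.4
    background_sigma_scale: float = 2.0  # pedestal blur, x nominal sigma x scale
    min_threshold: float = 0.15  # absolute floor on the corrected intensity

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not self.min_area_scale < self.max_area_scale:
            raise ValueError("min_area_scale must be < max_area_scale")


@dataclass
class CandidateRegion:
    """A connected bright compact region — the presumed kinetoplast."""

    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    area_px: int
    centroid: tuple[float, float]  # (x, y)
    max_intensity: float
    mean_intensity: float
    perimeter_px: float
    compactness: float

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("candidate region must contain at least one pixel")
        if self.max_intensity < self.mean_intensity - 1e-12:
            raise ValueError("max intensity below mean intensity")


def nominal_area(magnification_scale: float) -> float:
    """Expected kinetoplast area in px at a magnification scale."""
    return math.pi * (NOMINAL_KINETOPLAST_SIGMA * magnification_scale) ** 2


def correct_background(
    pixels: np.ndarray, magnification_scale: float, params: ScreeningParams
) -> np.ndarray:
    """Median-subtract, then remove the cell-body pedestal by unsharp masking."""
    corrected = np.clip(pixels - np.median(pixels), 0.0, None)
    sigma_bg = (
        params.background_sigma_scale * NOMINAL_KINETOPLAST_SIGMA * magnification_scale
    )
    highpass = corrected - ndimage.gaussian_filter(corrected, sigma_bg)
    return np.clip(highpass, 0.0, None)


def region_from_coords(
    coords: np.ndarray, intensities: np.ndarray
) -> CandidateRegion:
    """Build a CandidateRegion from (row, col) coordinates on an image."""
    coords = np.asarray(coords)
    rows, cols = coords[:, 0], coords[:, 1]
    vals = intensities[rows, cols]
    mask = np.zeros(
        (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1), dtype=bool
    )
    mask[rows - rows.min(), cols - cols.min()] = True
    perim = float(_perimeter(mask, neighborhood=4))
    area = int(coords.shape[0])
    compact = 4.0 * math.pi * area / perim**2 if perim > 0 else 1.0
    return CandidateRegion(
        coords=coords,
        area_px=area,
        centroid=(float(cols.mean()), float(rows.mean())),
        max_intensity=float(vals.max()),
        mean_intensity=float(vals.mean()),
        perimeter_px=perim,
        compactness=compact,
    )


def detect_candidates(
    image: WellImage, params: ScreeningParams | None = None
) -> list[CandidateRegion]:
    """Detect candidate kinetoplast regions in one canonical image.

    Returns regions sorted by max intensity (descending), ties broken by
    centroid (y, x), so downstream order is reproducible. A constant image
    yields an empty list.
    """
    params = params or ScreeningParams()
    corrected = correct_background(image.pixels, image.magnification_scale, params)
    sigma = float(corrected.std())
    if sigma == 0.0:
        return []
    # mu + k*sigma adapts to exposure and clutter; the absolute floor keeps
    # near-empty fields from collapsing the threshold below the faint
    # cell-body edge residue, which would merge spots into body-sized blobs
    threshold = max(
        float(corrected.mean()) + params.k_sigma * sigma, params.min_threshold
    )
    mask = corrected > threshold
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    nom = nominal_area(image.magnification_scale)
    min_area = params.min_area_scale * nom
    max_area = params.max_area_scale * nom
    regions = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        sub = labels[sl] == lab
        area = int(sub.sum())
        if not (min_area <= area <= max_area):
            continue
        rows, cols = np.nonzero(sub)
        coords = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        region = region_from_coords(coords, image.pixels)
        if region.compactness < params.min_compactness:
            continue
        regions.append(region)
    regions.sort(key=lambda r: (-r.max_intensity, r.centroid[1], r.centroid[0]))
    return regions


CANDIDATE_POSITIVE = "candidate_positive"
PRESUMED_NEGATIVE = "presumed_negative"


def prescreen_image(
    image: WellImage, params: ScreeningParams | None = None
) -> tuple[str, list[CandidateRegion]]:
    """Pre-screen an image: negative iff no candidate region is found.

    The ``candidate_positive`` outcome is a pre-screen, not a final label;
    the cell classifier downstream decides whether candidates are true
    kinetoplasts.
    """
    candidates = detect_candidates(image, params)
    label = CANDIDATE_POSITIVE if candidates else PRESUMED_NEGATIVE
    return label, candidates
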