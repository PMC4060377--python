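"""Per-cell feature vector: histogram, GLCM, Fourier, circular LBP, morphology.

The 60 features, in fixed order (block sizes in parentheses):

* histogram (5) — fraction of body pixels above the high-fluorescence
  threshold ``THETA_HF`` = 0.7, max, mean, std of body intensity, and the
  entropy (bits) of a 32-bin body histogram;
* GLCM (10) — contrast, correlation, energy, homogeneity, entropy of the
  symmetric, normalized gray-level co-occurrence matrix (32 levels),
  restricted to pixel pairs both inside the body mask, at distances 1 and 2,
  each averaged over the four axial/diagonal directions;
* Fourier (9) — fractions of power-spectrum energy in 8 equal radial annuli
  of the centered 64x64 spectrum (DC excluded) plus the spectral centroid
  radius. More fluorescent objects in a cell push energy outward;
* circular LBP (28) — rotation-invariant uniform local-binary-pattern
  histograms at (P=8, R=1) -> 10 bins and (P=16, R=2) -> 18 bins, computed
  over the eroded body interior and normalized to sum 1;
* morphology (8) — shape and intensity of the brightest candidate region:
  area fraction of the body, eccentricity, solidity, compactness,
  candidate/body mean-intensity ratio, candidate max intensity, centroid
  offset over the body major axis, and the candidate count.

Quantities with absolute scale are expressed as fractions or ratios so the
vector is robust to magnification: the same cell imaged at 25x and 50x
lands close in feature space.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern
from skimage.measure import regionprops

from .cells import CellCrop

logger = logging.getLogger(__name__)

THETA_HF = 0.7  # "high fluorescent" intensity threshold
GLCM_LEVELS = 32
GLCM_DISTANCES = (1, 2)
HIST_BINS = 32
FT_SIZE = 64
FT_BANDS = 8

# (dr, dc) offsets for angles 0, 45, 90, 135 degrees
_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FEATURE_NAMES: tuple[str, ...] = (
    ("hist_n_high_frac", "hist_max", "hist_mean", "hist_std", "hist_entropy")
    + tuple(
        f"glcm_{stat}_d{d}"
        for d in GLCM_DISTANCES
        for stat in ("contrast", "correlation", "energy", "homogeneity", "entropy")
    )
    + tuple(f"ft_band{i}" for i in range(FT_BANDS))
    + ("ft_centroid_radius",)
    + tuple(f"lbp_p8r1_{i}" for i in range(10))
    + tuple(f"lbp_p16r2_{i}" for i in range(18))
    + (
        "morph_area_fraction",
        "morph_eccentricity",
        "morph_solidity",
        "morph_compactness",
        "morph_mean_ratio",
        "morph_max_intensity",
        "morph_centroid_offset",
        "morph_candidate_count",
    )
)

N_FEATURES = len(FEATURE_NAMES)  # 60


def histogram_features(crop: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    if not body_mask.any():
        raise ValueError("empty body mask")
    vals = crop[body_mask]
    counts, _ = np.histogram(vals, bins=HIST_BINS, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return np.array(
        [
            float((vals > THETA_HF).mean()),
            float(vals.max()),
            float(vals.mean()),
            float(vals.std()),
            entropy,
        ]
    )


def _quantize(crop: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    return np.minimum((crop * levels).astype(np.int64), levels - 1)


def _glcm_matrix(
    q: np.ndarray, body_mask: np.ndarray, offset: tuple[int, int]
) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one offset, pairs
    restricted to the body mask; None when no valid pair exists."""
    dr, dc = offset
    h, w = q.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = q[r0, c0]
    b = q[r1, c1]
    valid = body_mask[r0, c0] & body_mask[r1, c1]
    if not valid.any():
        return None
    i, j = a[valid], b[valid]
    mat = np.zeros((GLCM_LEVELS, GLCM_LEVELS), dtype=np.float64)
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T  # symmetric
    return mat / mat.sum()


def _glcm_stats(mat: np.ndarray) -> np.ndarray:
    idx = np.arange(GLCM_LEVELS, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float((mat * (ii - jj) ** 2).sum())
    pi = mat.sum(axis=1)
    mu = float((idx * pi).sum())
    var = float(((idx - mu) ** 2 * pi).sum())
    if var > 0:
        correlation = float((mat * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 1.0  # degenerate single-level matrix
    energy = float((mat**2).sum())
    homogeneity = float((mat / (1.0 + (ii - jj) ** 2)).sum())
    nz = mat[mat > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.array([contrast, correlation, energy, homogeneity, entropy])


def glcm_features(crop: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    q = _quantize(crop)
    out = []
    for d in GLCM_DISTANCES:
        acc = []
        for angle, (dr, dc) in _GLCM_OFFSETS.items():
            mat = _glcm_matrix(q, body_mask, (dr * d, dc * d))
            if mat is not None:
                acc.append(_glcm_stats(mat))
        if acc:
            out.append(np.mean(acc, axis=0))
        else:
            logger.warning("no valid GLCM pairs at distance %d; features zeroed", d)
            out.append(np.zeros(5))
    return np.concatenate(out)


def fourier_features(crop: np.ndarray) -> np.ndarray:
    """Radial energy fractions + spectral centroid of the 64x64 spectrum."""
    patch = np.zeros((FT_SIZE, FT_SIZE), dtype=np.float64)
    h = min(crop.shape[0], FT_SIZE)
    w = min(crop.shape[1], FT_SIZE)
    r0 = (FT_SIZE - h) // 2
    c0 = (FT_SIZE - w) // 2
    cr = (crop.shape[0] - h) // 2
    cc = (crop.shape[1] - w) // 2
    patch[r0 : r0 + h, c0 : c0 + w] = crop[cr : cr + h, cc : cc + w]

    spec = np.fft.fftshift(np.fft.fft2(patch))
    power = np.abs(spec) ** 2
    cy = cx = FT_SIZE // 2
    ys, xs = np.mgrid[0:FT_SIZE, 0:FT_SIZE]
    r = np.hypot(ys - cy, xs - cx)
    ring = (r >= 1.0) & (r <= 32.0)  # DC excluded
    total = float(power[ring].sum())
    if total <= 0.0:
        return np.zeros(FT_BANDS + 1)
    edges = np.linspace(1.0, 32.0, FT_BANDS + 1)
    fracs = np.empty(FT_BANDS)
    for i in range(FT_BANDS):
        hi_inc = r <= edges[i + 1] if i == FT_BANDS - 1 else r < edges[i + 1]
        band = (r >= edges[i]) & hi_inc
        fracs[i] = power[band].sum() / total
    centroid = float((r[ring] * power[ring]).sum() / total)
    return np.append(fracs, centroid)


def lbp_features(crop: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    """Rotation-invariant uniform LBP histograms at (8,1) and (16,2)."""
    interior = ndimage.binary_erosion(body_mask, iterations=2)
    out = []
    for p, radius, n_bins in ((8, 1, 10), (16, 2, 18)):
        if not interior.any():
            out.append(np.zeros(n_bins))
            continue
        # 8-bit quantization: LBP compares neighbor intensities, and exact
        # ties behave predictably on integer data
        img8 = np.round(crop * 255.0).astype(np.uint8)
        codes = local_binary_pattern(img8, p, radius, method="uniform")
        vals = codes[interior].astype(np.int64)
        hist = np.bincount(vals, minlength=n_bins).astype(np.float64)
        out.append(hist / hist.sum())
    if not interior.any():
        logger.warning("body interior empty after erosion; LBP features zeroed")
    return np.concatenate(out)


def morphology_features(cell: CellCrop) -> np.ndarray:
    """Shape/intensity descriptors of the brightest candidate region."""
    if not cell.candidates_in_cell:
        raise ValueError("cell has no candidate region")
    cand = max(
        cell.candidates_in_cell,
        key=lambda c: (c.max_intensity, -c.centroid[1], -c.centroid[0]),
    )
    body_area = float(cell.body_mask.sum())
    body_mean = max(float(cell.crop[cell.body_mask].mean()), 1e-6)

    mask = np.zeros_like(cell.body_mask)
    rows, cols = cand.coords[:, 0], cand.coords[:, 1]
    keep = (rows < mask.shape[0]) & (cols < mask.shape[1])
    mask[rows[keep], cols[keep]] = True
    props = regionprops(mask.astype(np.uint8))[0]

    body_props = regionprops(cell.body_mask.astype(np.uint8))[0]
    major = max(float(body_props.axis_major_length), 1e-6)
    bc_y, bc_x = body_props.centroid
    offset = math.hypot(cand.centroid[0] - bc_x, cand.centroid[1] - bc_y) / major

    return np.array(
        [
            cand.area_px / max(body_area, 1.0),
            float(props.eccentricity),
            float(props.solidity),
            cand.compactness,
            cand.mean_intensity / body_mean,
            cand.max_intensity,
            offset,
            float(len(cell.candidates_in_cell)),
        ]
    )


def extract_features(cell: CellCrop) -> np.ndarray:
    """Concatenate all blocks into the fixed-order 60-vector."""
    vec = np.concatenate(
        [
            histogram_features(cell.crop, cell.body_mask),
            glcm_features(cell.crop, cell.body_mask),
            fourier_features(cell.crop),
            lbp_features(cell.crop, cell.body_mask),
            morphology_features(cell),
        ]
    )
    assert vec.shape == (N_FEATURES,)
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite features: {bad}")
    return vec
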