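"""Synthetic CLIFT well generator.

Emulates the statistical structure of a CLIFT acquisition campaign: each
serum occupies one well, each well is photographed in ~5 non-overlapping
fields, each field shows ~8 Crithidia luciliae cells. A positive serum
stains the kinetoplast — a small, very bright, compact spot near one pole
of the elongated cell body. Distractor fluorescence that real readers must
discount is rendered too: a dim broad nucleus at the cell center, a small
bright basal body adjacent to the kinetoplast pole, and extracellular
artifact speckles.

Serum status is a property of the well: every image of a well inherits the
well label, and in a positive well each cell independently carries a
kinetoplast with probability ``p_cell_positive_given_well_positive``
(default 0.9), so a minority of cells in positive wells are genuinely
negative — exactly the situation majority voting is meant to absorb.

All randomness flows from one ``numpy`` Generator seeded from
``SynthConfig.seed``; a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    NEGATIVE,
    POSITIVE,
    CellAnnotation,
    DatasetManifest,
    ManifestRecord,
    write_manifest,
)

ASPECT_RATIO = 2.5  # cell body length / width
KINETOPLAST_OFFSET_FRAC = 0.35  # kinetoplast pole site, fraction of body length


@dataclass
class SynthConfig:
    """Generation parameters; defaults emulate the reference acquisition."""

    seed: int = 0
    n_wells: int = 10
    fraction_positive_wells: float = 0.5
    images_per_well: int = 5
    mean_cells_per_image: float = 8.0
    image_size: tuple[int, int] = (512, 384)  # (width, height)
    magnification_scale: float = 1.0  # 1.0 = 50-fold reference, 0.5 = 25-fold
    cell_length_px: float = 40.0  # at scale 1.0
    kinetoplast_sigma_px: float = 2.5  # at scale 1.0
    kinetoplast_peak: float = 0.9
    p_cell_positive_given_well_positive: float = 0.9
    p_nucleus: float = 0.6
    p_basal_body: float = 0.3
    artifacts_per_image: float = 1.0
    noise_sigma: float = 0.02
    background_level: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "fraction_positive_wells",
            "p_cell_positive_given_well_positive",
            "p_nucleus",
            "p_basal_body",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.images_per_well < 1:
            raise ValueError("images_per_well must be >= 1")
        for name in (
            "mean_cells_per_image",
            "magnification_scale",
            "cell_length_px",
            "kinetoplast_sigma_px",
            "kinetoplast_peak",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kinetoplast_peak <= self.background_level:
            raise ValueError("kinetoplast_peak must exceed background_level")


@dataclass
class CellGeometry:
    """Ground-truth geometry and components of one rendered cell."""

    centroid: tuple[float, float]  # (x, y)
    length: float  # major-axis length, px
    orientation: float  # radians, ccw from +x axis
    cytoplasm: float
    label: str = NEGATIVE
    components: list[dict] = field(default_factory=list)  # rendered blobs

    @property
    def width(self) -> float:
        return self.length / ASPECT_RATIO

    def contains(self, x: np.ndarray, y: np.ndarray, margin: float = 0.0) -> np.ndarray:
        dx = x - self.centroid[0]
        dy = y - self.centroid[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        a = self.length / 2.0 + margin
        b = self.width / 2.0 + margin
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _add_gaussian(canvas: np.ndarray, x0: float, y0: float, sigma: float, peak: float) -> None:
    h, w = canvas.shape
    r = int(math.ceil(4 * sigma))
    x_lo, x_hi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    canvas[y_lo:y_hi, x_lo:x_hi] += peak * np.exp(
        -((xs - x0) ** 2 + (ys - y0) ** 2) / (2.0 * sigma**2)
    )


def render_cell(cell: CellGeometry, canvas: np.ndarray) -> list[tuple[float, float]]:
    """Draw one cell (body + components) additively onto ``canvas``.

    Rendering is additive with saturation handled by the caller's final clip
    at 1.0. Returns the centroids of the rendered components.
    """
    h, w = canvas.shape
    half = cell.length / 2.0
    x0, y0 = cell.centroid
    if not (half <= x0 <= w - 1 - half and half <= y0 <= h - 1 - half):
        raise ValueError(
            f"cell at {cell.centroid} with length {cell.length:.1f} exceeds "
            f"canvas {w}x{h}"
        )
    r = int(math.ceil(half)) + 1
    x_lo, x_hi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    body = cell.contains(xs.astype(float), ys.astype(float))
    canvas[y_lo:y_hi, x_lo:x_hi] += cell.cytoplasm * body
    centroids = []
    for comp in cell.components:
        cx, cy = comp["center"]
        _add_gaussian(canvas, cx, cy, comp["sigma"], comp["peak"])
        centroids.append((cx, cy))
    return centroids


def _draw_cell_count(rng: np.random.Generator, mean: float) -> int:
    # Poisson truncated at >= 1 by redrawing zeros
    for _ in range(1000):
        n = int(rng.poisson(mean))
        if n >= 1:
            return n
    return 1


def _place_cells(
    rng: np.random.Generator, cfg: SynthConfig, n_cells: int
) -> list[CellGeometry]:
    w, h = cfg.image_size
    scale = cfg.magnification_scale
    mean_len = cfg.cell_length_px * scale
    # the nucleus halo (sigma = 4 x kinetoplast sigma) fluoresces beyond the
    # body ellipse; keep neighbors apart so segmented bodies stay separable
    margin = max(5.0, 4.8 * cfg.kinetoplast_sigma_px * scale)
    cells: list[CellGeometry] = []
    for _ in range(n_cells):
        length = float(
            np.clip(rng.normal(mean_len, 0.15 * mean_len), 0.5 * mean_len, 1.5 * mean_len)
        )
        half = length / 2.0
        placed = None
        for _attempt in range(100):
            x = rng.uniform(half + 1, w - 2 - half)
            y = rng.uniform(half + 1, h - 2 - half)
            theta = rng.uniform(0.0, math.pi)
            cand = CellGeometry(
                centroid=(x, y),
                length=length,
                orientation=theta,
                cytoplasm=float(rng.uniform(0.15, 0.30)),
            )
            overlap = any(
                _bodies_overlap(cand, other, margin=margin) for other in cells
            )
            if not overlap:
                placed = cand
                break
        if placed is None:  # accept overlap after 100 retries
            placed = cand
        cells.append(placed)
    return cells


_ELLIPSE_T = np.linspace(0.0, 2.0 * math.pi, 32, endpoint=False)


def _bodies_overlap(a: CellGeometry, b: CellGeometry, margin: float = 5.0) -> bool:
    d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
    if d > (a.length + b.length) / 2.0 + margin:  # bounding circles disjoint
        return False
    for p, q in ((a, b), (b, a)):
        # boundary samples of p (with margin) falling inside q, or center in q
        c, s = math.cos(p.orientation), math.sin(p.orientation)
        u = (p.length / 2.0 + margin) * np.cos(_ELLIPSE_T)
        v = (p.width / 2.0 + margin) * np.sin(_ELLIPSE_T)
        xs = p.centroid[0] + u * c - v * s
        ys = p.centroid[1] + u * s + v * c
        if q.contains(xs, ys, margin=margin).any():
            return True
        if q.contains(
            np.array([p.centroid[0]]), np.array([p.centroid[1]]), margin=margin
        )[0]:
            return True
    return False


def _attach_components(
    rng: np.random.Generator, cfg: SynthConfig, cell: CellGeometry, well_positive: bool
) -> None:
    scale = cfg.magnification_scale
    sigma_k = cfg.kinetoplast_sigma_px * scale
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    pole = 1.0 if rng.random() < 0.5 else -1.0
    offset = KINETOPLAST_OFFSET_FRAC * cell.length * pole
    site = (cell.centroid[0] + offset * c, cell.centroid[1] + offset * s)

    is_positive = well_positive and (
        rng.random() < cfg.p_cell_positive_given_well_positive
    )
    if is_positive:
        cell.components.append(
            {"kind": "kinetoplast", "center": site, "sigma": sigma_k, "peak": cfg.kinetoplast_peak}
        )
        cell.label = POSITIVE
    if rng.random() < cfg.p_nucleus:
        cell.components.append(
            {
                "kind": "nucleus",
                "center": cell.centroid,
                "sigma": 4.0 * sigma_k,
                "peak": float(rng.uniform(0.35, 0.50)),
            }
        )
    if rng.random() < cfg.p_basal_body:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        d = 3.0 * sigma_k
        cell.components.append(
            {
                "kind": "basal_body",
                "center": (site[0] + d * math.cos(ang), site[1] + d * math.sin(ang)),
                "sigma": 0.6 * sigma_k,
                "peak": float(rng.uniform(0.5, 0.7)),
            }
        )


def render_image(
    rng: np.random.Generator, cfg: SynthConfig, well_positive: bool
) -> tuple[np.ndarray, list[CellGeometry]]:
    """Render one field: cells, distractors, artifacts, background, noise."""
    w, h = cfg.image_size
    canvas = np.zeros((h, w), dtype=np.float64)
    n_cells = _draw_cell_count(rng, cfg.mean_cells_per_image)
    cells = _place_cells(rng, cfg, n_cells)
    for cell in cells:
        _attach_components(rng, cfg, cell, well_positive)
        render_cell(cell, canvas)

    n_art = int(rng.poisson(cfg.artifacts_per_image))
    for _ in range(n_art):
        for _attempt in range(100):
            x = rng.uniform(2, w - 3)
            y = rng.uniform(2, h - 3)
            xa = np.asarray([x])
            ya = np.asarray([y])
            if not any(c.contains(xa, ya, margin=2.0)[0] for c in cells):
                break
        _add_gaussian(
            canvas,
            x,
            y,
            float(rng.uniform(1.0, 3.0)),
            float(rng.uniform(0.6, 1.0)),
        )

    canvas += cfg.background_level
    canvas += rng.normal(0.0, cfg.noise_sigma, size=canvas.shape)
    return np.clip(canvas, 0.0, 1.0), cells


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Generate a full synthetic dataset on disk and return its manifest.

    Writes 8-bit grayscale PNGs plus ``manifest.json`` (the JSON manifest
    dialect, with per-cell annotations at the true cell centroids).
    Deterministic given ``cfg.seed``: re-running produces identical bytes.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    records: list[ManifestRecord] = []
    for wi in range(cfg.n_wells):
        well_id = f"well{wi:03d}"
        well_positive = bool(rng.random() < cfg.fraction_positive_wells)
        well_label = POSITIVE if well_positive else NEGATIVE
        for ii in range(cfg.images_per_well):
            pixels, cells = render_image(rng, cfg, well_positive)
            img8 = np.round(pixels * 255.0).astype(np.uint8)
            name = f"{well_id}_img{ii:02d}.png"
            iio.imwrite(out_dir / name, img8)
            anns = tuple(
                CellAnnotation(x=c.centroid[0], y=c.centroid[1], label=c.label)
                for c in cells
            )
            records.append(
                ManifestRecord(
                    well_id=well_id,
                    image_path=name,
                    magnification_scale=cfg.magnification_scale,
                    image_label=well_label,  # image label follows serum status
                    well_label=well_label,
                    cells=anns,
                )
            )
    manifest = DatasetManifest(records=records, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest
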