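"""Candidate kinetoplast detection against a brute-force flood-fill oracle."""

import math

import numpy as np
import pytest
from skimage.measure import perimeter as sk_perimeter

from clift_cad.io import WellImage
from clift_cad.screening import (
    CANDIDATE_POSITIVE,
    PRESUMED_NEGATIVE,
    ScreeningParams,
    correct_background,
    detect_candidates,
    nominal_area,
    prescreen_image,
)
from clift_cad.synthesis import SynthConfig, generate_dataset
from clift_cad.io import load_record


def oracle_detect(image: WellImage, params: ScreeningParams):
    """Independent reimplementation: same threshold rule, but pure-Python
    BFS flood fill for the connected components and direct gate checks.
    Returns the set of frozensets of (row, col) pixels kept."""
    corrected = correct_background(image.pixels, image.magnification_scale, params)
    sigma = corrected.std()
    if sigma == 0:
        return set()
    t = max(corrected.mean() + params.k_sigma * sigma, params.min_threshold)
    mask = corrected > t
    h, w = mask.shape
    seen = np.zeros_like(mask)
    nom = nominal_area(image.magnification_scale)
    kept = set()
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            area = len(comp)
            if not params.min_area_scale * nom <= area <= params.max_area_scale * nom:
                continue
            rows = [p[0] for p in comp]
            cols = [p[1] for p in comp]
            sub = np.zeros((max(rows) - min(rows) + 1, max(cols) - min(cols) + 1), bool)
            for r, c in comp:
                sub[r - min(rows), c - min(cols)] = True
            perim = sk_perimeter(sub, neighborhood=4)
            compact = 4 * math.pi * area / perim**2 if perim > 0 else 1.0
            if compact < params.min_compactness:
                continue
            kept.add(frozenset(comp))
    return kept


def _well(pixels, scale=1.0):
    return WellImage("w", "i", pixels, scale)


class TestDetectCandidates:
    def test_all_zero_image_empty(self):
        assert detect_candidates(_well(np.zeros((64, 64)))) == []

    def test_constant_image_empty(self):
        assert detect_candidates(_well(np.full((64, 64), 0.4))) == []

    def test_single_gaussian_spot(self):
        ys, xs = np.mgrid[0:128, 0:128]
        spot = np.exp(-((xs - 50.3) ** 2 + (ys - 71.8) ** 2) / (2 * 2.0**2))
        img = np.clip(0.05 + spot, 0, 1)
        cands = detect_candidates(_well(img))
        assert len(cands) == 1
        cx, cy = cands[0].centroid
        assert math.hypot(cx - 50.3, cy - 71.8) <= 1.0
        # agrees with the flood-fill oracle
        oracle = oracle_detect(_well(img), ScreeningParams())
        assert {frozenset(map(tuple, c.coords)) for c in cands} == oracle

    def test_bright_line_rejected(self):
        img = np.full((128, 128), 0.05)
        img[60:63, 30:90] = 0.95
        params = ScreeningParams(max_area_scale=50.0)  # isolate the compactness gate
        assert detect_candidates(_well(img), params) == []
        # the line mask itself fails 4*pi*A/P^2
        mask = np.zeros((3, 60), bool)
        mask[:] = True
        perim = sk_perimeter(mask, neighborhood=4)
        assert 4 * math.pi * mask.sum() / perim**2 < 0.4

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = np.clip(rng.normal(0.1, 0.05, (64, 64)), 0, 1)
        for _ in range(rng.integers(0, 4)):
            x0, y0 = rng.uniform(8, 56, 2)
            s = rng.uniform(1.0, 4.0)
            ys, xs = np.mgrid[0:64, 0:64]
            img = np.clip(
                img + rng.uniform(0.4, 0.9) * np.exp(
                    -((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * s * s)
                ),
                0, 1,
            )
        well = _well(img)
        got = {frozenset(map(tuple, c.coords)) for c in detect_candidates(well)}
        assert got == oracle_detect(well, ScreeningParams())

    def test_sorted_by_brightness(self):
        ys, xs = np.mgrid[0:128, 0:128]
        img = 0.05 * np.ones((128, 128))
        img += 0.9 * np.exp(-((xs - 30) ** 2 + (ys - 30) ** 2) / 8)
        img += 0.6 * np.exp(-((xs - 90) ** 2 + (ys - 90) ** 2) / 8)
        cands = detect_candidates(_well(np.clip(img, 0, 1)))
        assert len(cands) == 2
        assert cands[0].max_intensity >= cands[1].max_intensity

    def test_monotone_in_k_sigma(self, dataset12):
        counts = []
        recs = dataset12.records[:4]
        for k in (4.0, 6.0, 8.0, 12.0):
            params = ScreeningParams(k_sigma=k)
            counts.append(
                sum(
                    len(detect_candidates(load_record(dataset12, r), params))
                    for r in recs
                )
            )
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPrescreen:
    def test_image_with_candidate_is_candidate_positive(self):
        ys, xs = np.mgrid[0:128, 0:128]
        img = np.clip(
            0.05 + np.exp(-((xs - 60) ** 2 + (ys - 60) ** 2) / 8), 0, 1
        )
        label, cands = prescreen_image(_well(img))
        assert label == CANDIDATE_POSITIVE and len(cands) == 1

    def test_blank_image_presumed_negative(self):
        label, cands = prescreen_image(_well(np.zeros((64, 64))))
        assert label == PRESUMED_NEGATIVE and cands == []

    def test_zero_false_negatives_on_synthetic_positives(self, tmp_path):
        # default conditions: kinetoplast contrast far above 6 noise SDs
        cfg = SynthConfig(seed=23, n_wells=6, fraction_positive_wells=1.0,
                          images_per_well=3)
        man = generate_dataset(cfg, tmp_path)
        for rec in man.records:
            if not any(c.label == "positive" for c in rec.cells):
                continue  # a positive well can hold an all-negative field
            label, _ = prescreen_image(load_record(man, rec))
            assert label == CANDIDATE_POSITIVE

    def test_some_negatives_leak_through(self, dataset12):
        # distractors and artifacts make some true-negative images
        # candidate_positive, as in the reference contingency table
        neg = [r for r in dataset12.records if r.well_label == "negative"]
        labels = [prescreen_image(load_record(dataset12, r))[0] for r in neg]
        assert CANDIDATE_POSITIVE in labels
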