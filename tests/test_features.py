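"""Feature blocks: frozen examples, oracles and invariance properties."""

import itertools
import math

import numpy as np
import pytest

from clift_cad.cells import extract_cells
from clift_cad.features import (
    FEATURE_NAMES,
    N_FEATURES,
    THETA_HF,
    _glcm_matrix,
    _glcm_stats,
    _quantize,
    extract_features,
    fourier_features,
    glcm_features,
    histogram_features,
    lbp_features,
    morphology_features,
)
from clift_cad.io import WellImage
from clift_cad.screening import detect_candidates, region_from_coords


def _full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestHistogram:
    def test_constant_crop(self):
        v = histogram_features(np.full((10, 10), 0.2), _full_mask((10, 10)))
        n_high, mx, mean, std, entropy = v
        assert n_high == 0.0
        assert mx == 0.2
        assert mean == pytest.approx(0.2)
        assert std == pytest.approx(0.0, abs=1e-12)
        assert entropy == 0.0

    def test_single_bright_pixel(self):
        crop = np.zeros((10, 10))
        crop[3, 7] = 1.0
        v = histogram_features(crop, _full_mask((10, 10)))
        assert v[0] == 0.01  # n_high_frac
        assert v[1] == 1.0  # max

    def test_entropy_bounded_by_log2_bins(self):
        rng = np.random.default_rng(0)
        crop = rng.uniform(0, 1, (32, 32))
        v = histogram_features(crop, _full_mask((32, 32)))
        assert 0.0 <= v[4] <= math.log2(32)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.zeros((5, 5)), np.zeros((5, 5), bool))


def glcm_oracle(q, mask, offset):
    """Brute-force pair enumeration over the mask."""
    h, w = q.shape
    dr, dc = offset
    mat = np.zeros((32, 32))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                mat[q[r, c], q[rr, cc]] += 1
    mat = mat + mat.T
    return mat / mat.sum() if mat.sum() else None


class TestGLCM:
    def test_constant_crop_degenerate_matrix(self):
        v = glcm_features(np.full((12, 12), 0.5), _full_mask((12, 12)))
        for d in range(2):
            contrast, corr, energy, homog, entropy = v[5 * d : 5 * d + 5]
            assert contrast == 0.0
            assert energy == 1.0
            assert homog == 1.0
            assert entropy == 0.0

    def test_checkerboard_contrast_is_31_squared(self):
        cb = (np.indices((8, 8)).sum(0) % 2).astype(float)  # levels {0, 31}
        mat = _glcm_matrix(_quantize(cb), _full_mask((8, 8)), (0, 1))
        assert _glcm_stats(mat)[0] == pytest.approx(31.0**2)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(4, 9), rng.integers(4, 9))
        crop = rng.uniform(0, 1, shape)
        mask = rng.random(shape) < 0.8
        q = _quantize(crop)
        for d in (1, 2):
            for offset in ((0, d), (-d, d), (-d, 0), (-d, -d)):
                got = _glcm_matrix(q, mask, offset)
                want = glcm_oracle(q, mask, offset)
                if want is None:
                    assert got is None
                else:
                    assert np.allclose(got, want)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        v = glcm_features(rng.uniform(0, 1, (16, 16)), _full_mask((16, 16)))
        for d in range(2):
            _, _, energy, _, entropy = v[5 * d : 5 * d + 5]
            assert 0.0 < energy <= 1.0
            assert entropy >= 0.0


class TestFourier:
    def test_all_zero_crop_is_all_zero(self):
        assert np.array_equal(fourier_features(np.zeros((64, 64))), np.zeros(9))

    def test_energy_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        v = fourier_features(rng.uniform(0, 1, (40, 52)))
        assert v[:8].sum() == pytest.approx(1.0, abs=1e-9)

    def test_more_objects_push_centroid_outward(self):
        ys, xs = np.mgrid[0:64, 0:64]

        def spot(cx, cy, a):
            return a * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * 3.0**2))

        one = spot(32, 32, 1.0)
        four = sum(spot(cx, cy, 0.25) for cx, cy in
                   ((20, 20), (44, 20), (20, 44), (44, 44)))
        assert fourier_features(four)[-1] > fourier_features(one)[-1]


class TestLBP:
    def test_constant_crop_mass_in_flat_bin(self):
        v = lbp_features(np.full((20, 20), 0.3), _full_mask((20, 20)))
        h8, h16 = v[:10], v[10:]
        assert h8[8] == pytest.approx(1.0)  # all-neighbors-equal bin
        assert h16[16] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_right_angle_rotation_invariance(self, k):
        rng = np.random.default_rng(7)
        crop = rng.uniform(0, 1, (24, 24))
        mask = np.zeros((24, 24), bool)
        mask[4:20, 6:18] = True
        a = lbp_features(crop, mask)
        b = lbp_features(np.rot90(crop, k).copy(), np.rot90(mask, k).copy())
        assert np.allclose(a, b, atol=1e-9)

    def test_histograms_sum_to_one(self):
        rng = np.random.default_rng(9)
        v = lbp_features(rng.uniform(0, 1, (30, 30)), _full_mask((30, 30)))
        assert v[:10].sum() == pytest.approx(1.0, abs=1e-9)
        assert v[10:].sum() == pytest.approx(1.0, abs=1e-9)


def _crop_with_candidates(cand_masks, crop=None):
    """Assemble a CellCrop whose candidates are the given boolean masks."""
    from clift_cad.cells import CellCrop

    shape = cand_masks[0].shape
    body = np.zeros(shape, bool)
    body[2:-2, 2:-2] = True
    if crop is None:
        crop = np.full(shape, 0.2)
        for m in cand_masks:
            crop[m] = 0.9
    cands = [
        region_from_coords(np.column_stack(np.nonzero(m)), crop) for m in cand_masks
    ]
    return CellCrop(
        well_id="w", image_id="i", crop=crop, body_mask=body,
        candidates_in_cell=cands, cell_centroid=(0, 0), major_axis_len=64.0,
        orientation=0.0, body_coords_image=np.column_stack(np.nonzero(body)),
    )


class TestMorphology:
    def test_circular_candidate_compactness(self):
        ys, xs = np.mgrid[0:64, 0:64]
        disk = (xs - 32) ** 2 + (ys - 32) ** 2 <= 4**2
        cell = _crop_with_candidates([disk])
        v = morphology_features(cell)
        compactness = v[3]
        assert 0.85 <= compactness <= 1.2

    def test_candidate_covering_body_has_area_fraction_one(self):
        body = np.zeros((64, 64), bool)
        body[2:-2, 2:-2] = True
        cell = _crop_with_candidates([body])
        assert morphology_features(cell)[0] == pytest.approx(1.0)

    def test_brightest_of_two_candidates_drives_shape(self):
        ys, xs = np.mgrid[0:64, 0:64]
        small = (xs - 20) ** 2 + (ys - 20) ** 2 <= 3**2
        big = (xs - 44) ** 2 + (ys - 44) ** 2 <= 6**2
        crop = np.full((64, 64), 0.2)
        crop[big] = 0.5
        crop[small] = 0.95  # brighter, smaller
        cell = _crop_with_candidates([small, big], crop=crop)
        v = morphology_features(cell)
        assert v[7] == 2.0  # candidate count
        assert v[5] == pytest.approx(0.95)  # max intensity of the brightest
        body_area = cell.body_mask.sum()
        assert v[0] == pytest.approx(small.sum() / body_area)


class TestExtractFeatures:
    def test_fixed_length_finite_and_named(self, table12):
        assert len(FEATURE_NAMES) == N_FEATURES == 60
        assert table12.X.shape[1] == 60
        assert np.all(np.isfinite(table12.X))

    def test_deterministic_per_crop(self, dataset12, processed12):
        from clift_cad.io import load_record

        ic = next(p for p in processed12 if p.crops)
        img = load_record(dataset12, ic.record)
        cands = detect_candidates(img)
        again = extract_cells(img, cands)
        assert np.allclose(extract_features(again[0]), ic.features[0])

    def test_bounded_features_respect_bounds(self, table12):
        idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        X = table12.X
        for name in ("hist_n_high_frac", "morph_area_fraction"):
            assert np.all((X[:, idx[name]] >= 0) & (X[:, idx[name]] <= 1))
        for name in [n for n in FEATURE_NAMES if n.startswith(("ft_band", "lbp_"))]:
            assert np.all((X[:, idx[name]] >= 0) & (X[:, idx[name]] <= 1))
        lbp8 = [idx[f"lbp_p8r1_{i}"] for i in range(10)]
        lbp16 = [idx[f"lbp_p16r2_{i}"] for i in range(18)]
        assert np.allclose(X[:, lbp8].sum(1), 1.0, atol=1e-9)
        assert np.allclose(X[:, lbp16].sum(1), 1.0, atol=1e-9)

    def test_key_features_separate_classes(self, table12):
        # rank-sum AUC of single features on labeled cells
        from scipy.stats import mannwhitneyu

        idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        mask = table12.labeled
        y = np.array([str(v) for v in table12.true_label[mask]])
        X = table12.X[mask]
        def auc(name):
            pos = X[y == "positive", idx[name]]
            neg = X[y == "negative", idx[name]]
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            return max(u, len(pos) * len(neg) - u) / (len(pos) * len(neg))

        # kinetoplast brightness separates cleanly
        assert auc("morph_max_intensity") > 0.9
        assert auc("hist_max") > 0.9
        # the basal-body distractor straddles the high-fluorescence
        # threshold by design, so this single feature is a weaker separator
        assert auc("hist_n_high_frac") > 0.75
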