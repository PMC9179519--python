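"""Radiomics: feature-vector contract, matrix oracles, closed forms, and
derived-image properties."""

import numpy as np
import pytest

from dualrad import (derive_images, extract_features, feature_names,
                     first_order_features, generate_phantom, glcm_features,
                     glcm_matrix, shape_features_2d)
from dualrad.phantom import PhantomConfig
from dualrad.radiomics import RadiomicsError, quantize


def brute_force_glcm(quant, mask, offset):
    """Exhaustive pixel-pair enumeration oracle for the co-occurrence matrix."""
    ng = int(quant.max())
    M = np.zeros((ng, ng))
    h, w = quant.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                M[quant[r, c] - 1, quant[r2, c2] - 1] += 1
                M[quant[r2, c2] - 1, quant[r, c] - 1] += 1  # symmetric pooling
    return M / M.sum() if M.sum() else M


class TestFeatureVector:
    def test_length_354_names_unique_values_finite(self, small_cohort):
        _, samples, _ = small_cohort
        lesion = next(s for s in samples if s.label == "malignant")
        rv = extract_features(lesion)
        assert len(rv.values) == 354
        assert len(rv.names) == 354
        assert len(set(rv.names)) == 354
        assert np.all(np.isfinite(rv.values))

    def test_deterministic(self, small_cohort):
        _, samples, _ = small_cohort
        lesion = next(s for s in samples if s.label == "benign")
        a = extract_features(lesion)
        b = extract_features(lesion)
        assert np.array_equal(a.values, b.values)

    def test_frozen_name_manifest_structure(self):
        names = feature_names()
        assert sum(n.startswith("original_firstorder") for n in names) == 18
        assert sum(n.startswith("original_shape2D") for n in names) == 9
        assert sum(n.startswith("original_glcm") for n in names) == 24
        assert sum(n.startswith("original_gldm") for n in names) == 14
        assert sum(n.startswith("original_glrlm") for n in names) == 16
        assert sum(n.startswith("original_glszm") for n in names) == 16
        assert sum(n.startswith("original_ngtdm") for n in names) == 5
        assert sum("_firstorder_" in n and not n.startswith("original")
                   for n in names) == 14 * 18

    def test_affine_intensity_invariance_of_texture_features(self, small_cohort):
        _, samples, _ = small_cohort
        lesion = next(s for s in samples if s.label == "malignant")
        a = extract_features(lesion)
        b = extract_features(0.5 * lesion.image + 0.1, mask=lesion.mask)
        tex = [i for i, n in enumerate(a.names)
               if any(f"_{fam}_" in n for fam in
                      ("glcm", "gldm", "glrlm", "glszm", "ngtdm"))]
        assert np.allclose(a.values[tex], b.values[tex], atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(RadiomicsError, match="empty mask"):
            extract_features(np.ones((8, 8)), mask=np.zeros((8, 8)))


class TestGLCM:
    def test_matrix_matches_exhaustive_pair_enumeration(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 1, (4, 4))
            mask = np.ones((4, 4), dtype=np.uint8)
            quant = quantize(img, 4)
            for off in ((0, 1), (1, 0), (1, 1), (1, -1)):
                got = glcm_matrix(quant, mask, off)
                want = brute_force_glcm(quant, mask, off)
                assert np.allclose(got, want, atol=1e-12)

    def test_contrast_from_oracle_on_toy_raster(self):
        img = np.array([[0.0, 0.1, 0.2, 0.3],
                        [0.3, 0.2, 0.1, 0.0],
                        [0.0, 0.3, 0.1, 0.2],
                        [0.2, 0.0, 0.3, 0.1]])
        mask = np.ones((4, 4), dtype=np.uint8)
        quant = quantize(img, 4)
        feats = glcm_features(quant, mask)
        # independent contrast computation from the enumerated matrices
        contrasts = []
        for off in ((0, 1), (1, 1), (1, 0), (1, -1)):
            P = brute_force_glcm(quant, mask, off)
            i, j = np.meshgrid(np.arange(1, 5), np.arange(1, 5), indexing="ij")
            contrasts.append((((i - j) ** 2) * P).sum())
        assert feats["Contrast"] == pytest.approx(np.mean(contrasts), abs=1e-12)

    def test_checkerboard_contrast_is_one(self):
        cb = (np.indices((8, 8)).sum(axis=0) % 2) + 1
        P = glcm_matrix(cb, np.ones((8, 8), np.uint8), (0, 1))
        i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
        assert (((i - j) ** 2) * P).sum() == pytest.approx(1.0)

    def test_matrix_normalized(self, rng):
        quant = quantize(rng.uniform(0, 1, (6, 6)), 5)
        P = glcm_matrix(quant, np.ones((6, 6), np.uint8), (1, 0))
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_roi_conventions(self):
        quant = np.ones((5, 5), dtype=np.int64)
        feats = glcm_features(quant, np.ones((5, 5), np.uint8))
        assert feats["Contrast"] == 0.0
        assert feats["MaximumProbability"] == 1.0
        assert feats["JointEntropy"] == 0.0


class TestFirstOrder:
    def test_hand_computed_toy_values(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        fo = first_order_features(v, n_bins=4)
        assert fo["Mean"] == 2.5
        assert fo["Variance"] == 1.25
        assert fo["Range"] == 3.0
        assert fo["Energy"] == 30.0
        assert fo["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert fo["Skewness"] == 0.0
        assert fo["Entropy"] == pytest.approx(2.0)   # 4 equally filled bins
        assert fo["Uniformity"] == pytest.approx(0.25)

    def test_constant_roi_closed_forms(self):
        fo = first_order_features(np.full(30, 0.7))
        assert fo["Mean"] == pytest.approx(0.7)
        assert fo["Variance"] == pytest.approx(0.0, abs=1e-30)
        assert fo["Entropy"] == 0.0
        assert fo["Uniformity"] == 1.0
        assert fo["Skewness"] == 0.0 and fo["Kurtosis"] == 0.0


class TestShape2D:
    def test_filled_square_area(self):
        m = np.zeros((20, 20), np.uint8)
        m[5:15, 5:15] = 1
        sh = shape_features_2d(m)
        assert sh["PixelArea"] == 100.0

    def test_disk_isoperimetric_ratio(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 20 ** 2).astype(np.uint8)
        sh = shape_features_2d(disk)
        ratio = sh["Perimeter"] ** 2 / sh["PixelArea"]
        assert ratio == pytest.approx(4 * np.pi, rel=0.15)

    def test_rotation_by_90_degrees_is_exact_symmetry(self):
        rng = np.random.default_rng(4)
        m = np.zeros((40, 40), np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        m[((yy - 18) / 9.0) ** 2 + ((xx - 22) / 5.0) ** 2 <= 1] = 1
        a = shape_features_2d(m)
        b = shape_features_2d(np.rot90(m).copy())
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_empty_mask_rejected(self):
        with pytest.raises(RadiomicsError):
            shape_features_2d(np.zeros((5, 5), np.uint8))


class TestDerivedImages:
    def test_constant_image_has_zero_log_response(self):
        d = derive_images(np.full((24, 24), 0.5))
        assert np.allclose(d["log-sigma-1"], 0.0, atol=1e-12)
        assert np.allclose(d["log-sigma-3"], 0.0, atol=1e-12)

    def test_exactly_14_rasters_with_input_shape(self):
        img = np.random.default_rng(0).uniform(0, 1, (50, 50))  # not 8-divisible
        d = derive_images(img)
        assert len(d) == 14
        assert all(v.shape == (50, 50) for v in d.values())
        levels = {n.split("-")[1] for n in d if n.startswith("wavelet")}
        assert levels == {"L1", "L2", "L3"}

    def test_impulse_log_response_equals_analytic_kernel(self):
        imp = np.zeros((41, 41))
        imp[20, 20] = 1.0
        resp = derive_images(imp)["log-sigma-1"]
        # independent closed-form oracle evaluated on the grid
        sigma = 1.0
        yy, xx = np.mgrid[0:41, 0:41] - 20.0
        r2 = xx ** 2 + yy ** 2
        analytic = ((r2 - 2 * sigma ** 2) / (2 * np.pi * sigma ** 6)
                    * np.exp(-r2 / (2 * sigma ** 2)))
        assert np.abs(resp - analytic).max() < 1e-6

    def test_non_2d_input_rejected(self):
        with pytest.raises(RadiomicsError):
            derive_images(np.zeros((4, 4, 2)))


class TestClassSeparation:
    def test_some_texture_feature_separates_benign_from_malignant(self):
        """Spiculated boundaries change intensity/texture statistics inside
        the ROI enough for a rank-sum test to notice at n=30 per class."""
        from dualrad import per_feature_wilcoxon

        cfg = PhantomConfig(image_size=64, n_benign=30, n_malignant=30,
                            n_normal=0, seed=8)
        feats, labels = [], []
        for i in range(30):
            for lab in ("benign", "malignant"):
                s = generate_phantom(lab, cfg, i)
                feats.append(extract_features(s).values)
                labels.append(int(lab == "malignant"))
        X = np.vstack(feats)
        names = feature_names()
        glcm_cols = [i for i, n in enumerate(names) if "_glcm_" in n]
        table = per_feature_wilcoxon(X[:, glcm_cols], np.array(labels))
        assert table["p_value"].min() < 0.05
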