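import math

import numpy as np
import pytest

from semmorph import (
    GLCMConfig,
    Micrograph,
    ValidationError,
    descriptors,
    glcm,
    image_descriptors,
    quantize,
    texture_map,
)
from semmorph.synthetic import gen_texture

OFF01 = GLCMConfig(levels=2, offsets=((0, 1),))


class TestQuantize:
    def test_endpoints_map_to_extreme_levels(self):
        arr = np.array([[0, 255]], dtype=np.uint8)
        np.testing.assert_array_equal(quantize(arr, 8, bit_depth=8), [[0, 7]])

    def test_constant_image_single_level(self):
        arr = np.full((10, 10), 77, dtype=np.uint8)
        assert len(np.unique(quantize(arr, 16, bit_depth=8))) == 1

    def test_midpoint_floor_binning(self):
        arr = np.array([[128]], dtype=np.uint8)
        assert quantize(arr, 8, bit_depth=8)[0, 0] == 4  # floor(128*8/256)

    def test_full_range_binning_not_observed_range(self):
        # identical binning regardless of the values present in the image
        a = np.array([[10, 20]], dtype=np.uint8)
        b = np.array([[10, 20, 250]], dtype=np.uint8)
        qa, qb = quantize(a, 16, bit_depth=8), quantize(b, 16, bit_depth=8)
        np.testing.assert_array_equal(qa[0], qb[0, :2])


class TestGLCM:
    def test_constant_image_all_mass_on_diagonal(self):
        q = np.zeros((8, 8), dtype=int)
        p = glcm(q, GLCMConfig(levels=2, offsets=((0, 1),)))
        assert p[0, 0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_checkerboard_direct_enumeration(self):
        i = np.arange(8)
        q = ((i[:, None] + i[None, :]) % 2).astype(int)
        p = glcm(q, OFF01)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        assert p[0, 0] == p[1, 1] == 0.0

    def test_matches_skimage_reference(self):
        # independent oracle: scikit-image's co-occurrence accumulator
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(0)
        q = rng.integers(0, 8, size=(32, 32)).astype(np.uint8)
        mine = glcm(q, GLCMConfig(levels=8, offsets=((0, 1),), symmetric=True, normalize=True))
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 4, size=(16, 16))
        p = glcm(q, GLCMConfig(levels=4, offsets=((1, 1),), symmetric=True))
        np.testing.assert_allclose(p, p.T)

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValidationError):
            glcm(np.zeros((4, 4), dtype=int), GLCMConfig(levels=2, offsets=((0, 5),)))


class TestDescriptors:
    def test_constant_image_analytic_values(self):
        img, truth = gen_texture("constant", canvas_px=32)
        d = image_descriptors(img, GLCMConfig(levels=8, offsets=((0, 1),)))
        assert d.asm == 1.0
        assert d.entropy == 0.0
        assert d.contrast == 0.0
        assert d.idm == 1.0
        assert d.correlation is None
        rec = truth.records[0]
        assert rec["glcm_asm"] == 1.0 and rec["glcm_correlation"] is None

    def test_checkerboard_analytic_values(self):
        img, truth = gen_texture("checkerboard", canvas_px=32, period_px=1)
        d = image_descriptors(img, OFF01)
        rec = truth.records[0]
        assert d.asm == pytest.approx(rec["glcm_asm"])  # 0.5
        assert d.entropy == pytest.approx(math.log(2))
        assert d.contrast == pytest.approx(1.0)
        assert d.idm == pytest.approx(0.5)
        assert d.correlation == pytest.approx(-1.0)

    def test_transpose_invariance_of_symmetric_descriptors(self):
        rng = np.random.default_rng(2)
        p = rng.random((6, 6))
        p = p + p.T
        p /= p.sum()
        a, b = descriptors(p), descriptors(p.T)
        for name in ("asm", "entropy", "contrast", "idm", "correlation"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError):
            descriptors(np.ones((4, 4)))

    def test_entropy_asm_opposition_under_noise_sweep(self):
        # stronger noise -> flatter pair distribution: entropy up, ASM down
        prev_entropy, prev_asm = -1.0, 2.0
        cfg = GLCMConfig(levels=16, offsets=((0, 1),))
        for sd in (2.0, 10.0, 40.0):
            img, _ = gen_texture("gaussian_noise", canvas_px=128, noise_sd=sd, seed=5)
            d = image_descriptors(img, cfg)
            assert d.entropy > prev_entropy
            assert d.asm < prev_asm
            assert d.entropy <= math.log(16**2)  # uniform-distribution bound
            prev_entropy, prev_asm = d.entropy, d.asm

    def test_contrast_monotone_in_noise_level(self):
        cfg = GLCMConfig(levels=16, offsets=((0, 1),))
        img_lo, _ = gen_texture("gaussian_noise", noise_sd=5.0, seed=7)
        img_hi, _ = gen_texture("gaussian_noise", noise_sd=30.0, seed=7)
        assert image_descriptors(img_hi, cfg).contrast > image_descriptors(img_lo, cfg).contrast

    def test_invariant_to_subquantization_intensity_shift(self):
        rng = np.random.default_rng(4)
        base = (rng.integers(0, 15, size=(32, 32)) * 16).astype(np.uint8)
        cfg = GLCMConfig(levels=16, offsets=((0, 1),))
        d0 = image_descriptors(base, cfg, bit_depth=8)
        d1 = image_descriptors(base + 7, cfg, bit_depth=8)  # below the 16-value bin width
        assert d0.asm == d1.asm and d0.contrast == d1.contrast


class TestTextureMap:
    def test_two_noise_halves_separated_by_contrast(self):
        rng = np.random.default_rng(11)
        left = rng.normal(128, 4, (96, 48))
        right = rng.normal(128, 45, (96, 48))
        pix = np.clip(np.round(np.hstack([left, right])), 0, 255).astype(np.uint8)
        m = Micrograph(pix, 8, 0.1)
        maps = texture_map(m, window_px=24, stride=24, config=GLCMConfig(levels=16, offsets=((0, 1),)))
        contrast = maps["contrast"]
        left_vals, right_vals = contrast[:, :2].ravel(), contrast[:, 2:].ravel()
        threshold = (left_vals.max() + right_vals.min()) / 2
        assert left_vals.max() < threshold < right_vals.min()

    def test_whole_image_window_matches_global_descriptors(self):
        img, _ = gen_texture("gaussian_noise", canvas_px=64, seed=9)
        cfg = GLCMConfig(levels=8, offsets=((0, 1),))
        maps = texture_map(img, window_px=64, stride=1, config=cfg)
        whole = image_descriptors(img, cfg)
        assert maps["entropy"].shape == (1, 1)
        assert maps["entropy"][0, 0] == pytest.approx(whole.entropy)
        assert maps["contrast"][0, 0] == pytest.approx(whole.contrast)

    def test_constant_image_constant_maps(self):
        img, _ = gen_texture("constant", canvas_px=64)
        maps = texture_map(img, window_px=16, stride=16)
        assert (maps["asm"] == 1.0).all()
        assert (maps["contrast"] == 0.0).all()
        assert np.isnan(maps["correlation"]).all()

    def test_window_normalization_conserved(self):
        img, _ = gen_texture("gaussian_noise", canvas_px=48, seed=13)
        q = quantize(img, 8)
        for r in (0, 16):
            p = glcm(q[r : r + 16, r : r + 16], GLCMConfig(levels=8))
            assert p.sum() == pytest.approx(1.0)

    def test_window_too_small_rejected(self):
        img, _ = gen_texture("constant", canvas_px=32)
        with pytest.raises(ValidationError):
            texture_map(img, window_px=2, stride=1)
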