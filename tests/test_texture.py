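"""Texture features vs closed forms, brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntcc import texture
from oracles import (
    coarseness_oracle,
    contrast_oracle,
    directionality_histogram_oracle,
    eoh_oracle,
    glcm_oracle,
    haralick_oracle,
    lbp_codes_oracle,
)


def random_image(seed, shape=(16, 16)):
    return np.random.default_rng(seed).integers(0, 256, size=shape).astype(np.uint8)


# ---------------------------------------------------------------------------
# GLCM + Haralick
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_constant_image_single_entry(self):
        img = np.full((4, 4), 100, dtype=np.uint8)
        g = texture.compute_glcm(img, levels=8, offsets=((0, 1),))
        q = (100 * 8) // 256
        assert g.p[q, q] == pytest.approx(1.0)
        assert np.count_nonzero(g.p) == 1

    def test_checker_2x2_antidiagonal(self):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        g = texture.compute_glcm(img, levels=2, offsets=((0, 1),))
        assert np.allclose(g.p, [[0, 0.5], [0.5, 0]])

    def test_probabilities_sum_to_one_and_symmetric(self, random_patch):
        g = texture.compute_glcm(random_patch)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g.p, g.p.T)
        assert g.p_sum.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.p_diff.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_pair_enumeration(self, seed):
        img = random_image(seed)
        mask = np.random.default_rng(seed + 100).random((16, 16)) > 0.3
        g = texture.compute_glcm(img, mask)
        expected = glcm_oracle(img, mask)
        assert np.array_equal(g.p, expected) or np.allclose(g.p, expected, atol=1e-15)

    def test_no_valid_pairs_errors(self):
        img = random_image(3, (4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True  # a lone pixel has no pair at distance 1
        with pytest.raises(ValueError):
            texture.compute_glcm(img, mask)


class TestHaralick:
    def test_constant_image_closed_forms(self):
        img = np.full((8, 8), 42, dtype=np.uint8)
        hf = texture.haralick_features(texture.compute_glcm(img))
        assert hf.asm == pytest.approx(1.0)
        assert hf.contrast == pytest.approx(0.0)
        assert hf.idm == pytest.approx(1.0)
        assert hf.entropy == pytest.approx(0.0)
        assert hf.correlation == 0.0  # degenerate marginals convention

    def test_two_entry_glcm_closed_forms(self):
        g = texture.GLCM(p=np.array([[0, 0.5], [0.5, 0]]), levels=2,
                         offsets=((0, 1),))
        hf = texture.haralick_features(g)
        assert hf.asm == pytest.approx(0.5)
        assert hf.contrast == pytest.approx(1.0)  # every pair differs by 1
        assert hf.entropy == pytest.approx(1.0)  # one bit

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        g = texture.compute_glcm(random_image(seed))
        got = texture.haralick_features(g).as_array()
        expected = haralick_oracle(g.p)
        assert np.allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_range_invariants(self, random_patch):
        hf = texture.haralick_features(texture.compute_glcm(random_patch))
        assert 0 < hf.asm <= 1
        assert hf.contrast >= 0
        assert -1 <= hf.correlation <= 1
        assert hf.sum_entropy >= 0 and hf.difference_entropy >= 0
        assert 0 <= hf.entropy <= 2 * np.log2(16)


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

class TestLBP:
    def test_flat_patch_codes_to_all_ones(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        codes, _ = texture.lbp_codes(img, P=8, R=1.0)
        assert np.all(codes == 255)  # s(0) = 1 for every neighbor

    def test_bright_center_on_dark_field_codes_zero(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        codes, _ = texture.lbp_codes(img, mask, P=8, R=1.0)
        assert codes.tolist() == [0]

    @pytest.mark.parametrize("seed", range(3))
    def test_codes_match_per_pixel_loop_oracle(self, seed):
        img = random_image(seed)
        codes, _ = texture.lbp_codes(img, P=8, R=1.0)
        assert sorted(codes.tolist()) == sorted(lbp_codes_oracle(img))

    def test_histogram_normalized(self, random_patch):
        for scheme, nbins in (("raw", 256), ("uniform", 59)):
            h = texture.lbp_histogram(random_patch, P=8, R=1.0, scheme=scheme)
            assert h.counts.size == nbins
            assert h.frequencies.sum() == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 3.0), st.integers(1, 50))
    def test_monotone_transform_invariance(self, seed, gain, offset):
        """LBP codes depend only on intensity orderings, so any strictly
        increasing gray-level transform leaves them unchanged."""
        img = np.random.default_rng(seed).integers(0, 200, (12, 12))
        transformed = (img.astype(float) * gain + offset)
        c1, _ = texture.lbp_codes(img.astype(float))
        c2, _ = texture.lbp_codes(transformed)
        assert np.array_equal(c1, c2)

    def test_too_small_region_errors(self):
        with pytest.raises(ValueError):
            texture.lbp_codes(np.zeros((2, 2), dtype=np.uint8), P=8, R=1.0)


# ---------------------------------------------------------------------------
# Tamura
# ---------------------------------------------------------------------------

def checkerboard(block, shape=(64, 64), lo=0, hi=255):
    r = np.arange(shape[0])[:, None] // block
    c = np.arange(shape[1])[None, :] // block
    return np.where((r + c) % 2 == 0, lo, hi).astype(np.uint8)


class TestTamura:
    def test_constant_coarseness_tie_breaks_to_smallest_window(self):
        img = np.full((40, 40), 9, dtype=np.uint8)
        assert texture.tamura_coarseness(img) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_coarseness_matches_nested_loop_oracle(self, seed):
        img = random_image(seed)
        got = texture.tamura_coarseness(img)
        assert got == pytest.approx(coarseness_oracle(img), rel=1e-9)

    def test_coarseness_increases_with_pattern_scale(self):
        fine = texture.tamura_coarseness(checkerboard(2, (80, 80)))
        coarse = texture.tamura_coarseness(checkerboard(16, (80, 80)))
        assert coarse > fine

    def test_coarseness_too_small_region_errors(self):
        with pytest.raises(ValueError):
            texture.tamura_coarseness(np.zeros((4, 4), dtype=np.uint8))

    def test_contrast_symmetric_two_point(self):
        img = np.repeat([0, 255], 50).astype(np.uint8).reshape(10, 10)
        # alpha4 = 1 for a symmetric two-point distribution -> Fcon = sigma
        assert texture.tamura_contrast(img) == pytest.approx(127.5)

    def test_contrast_constant_zero(self):
        assert texture.tamura_contrast(np.full((8, 8), 5, dtype=np.uint8)) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_contrast_matches_loop_oracle(self, seed):
        img = np.random.default_rng(seed).normal(128, 30, (16, 16))
        got = texture.tamura_contrast(img)
        assert got == pytest.approx(contrast_oracle(img), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_directionality_histogram_matches_oracle(self, seed):
        img = random_image(seed)
        got = texture.directionality_histogram(img, threshold=12.0)
        expected = directionality_histogram_oracle(img, threshold=12.0)
        assert np.allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_stripes_more_directional_than_noise(self):
        stripes = np.tile(np.repeat([0, 255], 4), (64, 1))[:, :64].astype(np.uint8)
        noise = random_image(5, (64, 64))
        d_stripes = texture.tamura_directionality(stripes)
        d_noise = texture.tamura_directionality(noise)
        assert d_stripes > 0.9
        assert d_stripes > d_noise

    def test_flat_image_directionality_zero(self):
        assert texture.tamura_directionality(np.full((32, 32), 7, np.uint8)) == 0.0


# ---------------------------------------------------------------------------
# EOH
# ---------------------------------------------------------------------------

class TestEOH:
    def test_vertical_step_edge_maps_to_zero_degrees(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 255  # vertical edge: horizontal gradient, V = 0
        eoh = texture.edge_orientation_histogram(img, bins=8, threshold=1.0)
        freqs = eoh.frequencies
        zero_bin = 3  # (-22.5, 0] contains 0 degrees
        assert freqs[zero_bin] == pytest.approx(1.0)

    def test_horizontal_step_edge_maps_to_ninety_degrees(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[8:, :] = 255  # horizontal edge: H = 0 -> arctan limit 90
        eoh = texture.edge_orientation_histogram(img, bins=8, threshold=1.0)
        assert eoh.frequencies[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_pixel_loop_oracle(self, seed):
        img = random_image(seed)
        eoh = texture.edge_orientation_histogram(img, bins=8, threshold=50.0)
        expected = eoh_oracle(img, bins=8, threshold=50.0)
        assert np.array_equal(eoh.counts, expected)

    def test_flat_image_empty_histogram_entropy_zero(self):
        eoh = texture.edge_orientation_histogram(np.full((16, 16), 3, np.uint8))
        assert eoh.counts.sum() == 0
        assert eoh.entropy == 0.0

    def test_frequencies_sum_to_one_when_edges_exist(self, random_patch):
        eoh = texture.edge_orientation_histogram(random_patch)
        assert eoh.frequencies.sum() == pytest.approx(1.0)


def test_texture_features_translation_invariant():
    """Features of a masked region do not change when the whole region is
    translated inside the frame."""
    rng = np.random.default_rng(21)
    patch = rng.integers(0, 256, (20, 20)).astype(np.uint8)
    base = np.zeros((48, 48), dtype=np.uint8)
    shifted = np.zeros((48, 48), dtype=np.uint8)
    base[4:24, 4:24] = patch
    shifted[20:40, 17:37] = patch
    m1 = np.zeros((48, 48), bool)
    m1[4:24, 4:24] = True
    m2 = np.zeros((48, 48), bool)
    m2[20:40, 17:37] = True

    g1 = texture.haralick_features(texture.compute_glcm(base, m1)).as_array()
    g2 = texture.haralick_features(texture.compute_glcm(shifted, m2)).as_array()
    assert np.allclose(g1, g2)
    h1 = texture.lbp_histogram(base, m1)
    h2 = texture.lbp_histogram(shifted, m2)
    assert np.array_equal(h1.counts, h2.counts)
    assert texture.tamura_coarseness(base, m1) == texture.tamura_coarseness(shifted, m2)
    e1 = texture.edge_orientation_histogram(base, m1, threshold=30.0)
    e2 = texture.edge_orientation_histogram(shifted, m2, threshold=30.0)
    assert np.array_equal(e1.counts, e2.counts)
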