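"""Grayscale, padding and NCC correctness against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr
from skimage.feature import match_template as skimage_match

from trapmatch import imaging_core as ic
from trapmatch.errors import DegeneratePatchError, DegenerateTemplateError


class TestToGrayscale:
    def test_rgb_keeps_dimensions(self, rng):
        img = rng.integers(0, 256, (96, 128, 3)).astype(np.uint8)
        gray = ic.to_grayscale(img)
        assert gray.shape == (96, 128)
        assert np.isfinite(gray).all() and gray.min() >= 0 and gray.max() <= 255

    def test_gray_input_passes_through(self, rng):
        img = rng.integers(0, 256, (10, 12)).astype(np.uint8)
        np.testing.assert_array_equal(ic.to_grayscale(img), img)

    def test_uniform_channels_map_to_channel_value(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        np.testing.assert_allclose(ic.to_grayscale(img), 77.0, atol=1e-12)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            ic.to_grayscale(np.zeros((5, 5, 2)))


class TestPadImage:
    def test_nominal_trap_geometry(self):
        img = np.zeros((960, 1280))
        padded = ic.pad_image(img, np.zeros((144, 200)))
        assert padded.shape == (1104, 1480)

    @pytest.mark.parametrize("ih,iw,th,tw", [(10, 10, 2, 4), (33, 17, 5, 5),
                                             (8, 9, 8, 9), (20, 31, 1, 1)])
    def test_dimensions_and_center_recovery(self, rng, ih, iw, th, tw):
        img = rng.integers(0, 256, (ih, iw)).astype(float)
        padded = ic.pad_image(img, np.zeros((th, tw)))
        assert padded.shape == (ih + th, iw + tw)
        crop = padded[th // 2:th // 2 + ih, tw // 2:tw // 2 + iw]
        np.testing.assert_array_equal(crop, img)

    def test_median_fill_border(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(float)
        padded = ic.pad_image(img, np.zeros((2, 4)), fill="median")
        assert padded.shape == (12, 14)
        assert padded[0, 0] == np.median(img)
        assert padded[-1, -1] == np.median(img)

    def test_constant_and_edge_fill(self, rng):
        img = rng.integers(0, 256, (6, 6)).astype(float)
        assert ic.pad_image(img, np.zeros((2, 2)), fill=7.0)[0, 0] == 7.0
        edge = ic.pad_image(img, np.zeros((2, 2)), fill="edge")
        assert edge[0, 1] == img[0, 0]

    def test_oversized_template_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            ic.pad_image(np.zeros((5, 5)), np.zeros((6, 6)))


class TestNormalizePatch:
    def test_hand_computed_example(self):
        out = ic.normalize_patch(np.array([[0.0, 2.0], [0.0, 2.0]]))
        np.testing.assert_allclose(out, [[-0.5, 0.5], [-0.5, 0.5]], atol=1e-12)

    def test_constant_patch_is_degenerate(self):
        with pytest.raises(DegeneratePatchError):
            ic.normalize_patch(np.full((3, 3), 9.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 255), min_size=4, max_size=36).filter(
        lambda v: len(set(v)) > 1))
    def test_zero_sum_unit_energy(self, values):
        n = len(values)
        h = 2 if n % 2 == 0 else 1
        patch = np.array(values, dtype=float).reshape(h, n // h)
        out = ic.normalize_patch(patch)
        assert abs(out.sum()) < 1e-9
        assert abs((out ** 2).sum() - 1.0) < 1e-9


class TestNccAt:
    def test_self_correlation_is_one(self, rng):
        tpl = rng.integers(0, 256, (4, 6)).astype(float)
        img = rng.integers(0, 256, (12, 12)).astype(float)
        img[3:7, 2:8] = tpl
        assert ic.ncc_at(img, tpl, 2, 3) == pytest.approx(1.0, abs=1e-9)

    def test_inverted_window_scores_minus_one(self, rng):
        tpl = rng.integers(0, 256, (4, 6)).astype(float)
        img = np.zeros((10, 10))
        img[1:5, 1:7] = 255.0 - tpl
        assert ic.ncc_at(img, tpl, 1, 1) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_pearson_correlation(self, rng):
        """The coefficient is the Pearson r of template vs. window pixels."""
        img = rng.integers(0, 256, (8, 8)).astype(float)
        tpl = rng.integers(0, 256, (3, 3)).astype(float)
        for x, y in [(0, 0), (2, 3), (5, 5)]:
            window = img[y:y + 3, x:x + 3]
            expected = pearsonr(tpl.ravel(), window.ravel()).statistic
            assert ic.ncc_at(img, tpl, x, y) == pytest.approx(expected, abs=1e-9)

    def test_constant_window_scores_degenerate_value(self):
        tpl = np.arange(6, dtype=float).reshape(2, 3)
        img = np.full((8, 8), 5.0)
        assert ic.ncc_at(img, tpl, 0, 0) == 0.0
        assert ic.ncc_at(img, tpl, 0, 0, degenerate_value=-2.0) == -2.0

    def test_constant_template_raises(self):
        with pytest.raises(DegenerateTemplateError):
            ic.ncc_at(np.arange(64, dtype=float).reshape(8, 8),
                      np.full((2, 2), 3.0), 0, 0)


class TestMatchTemplate:
    def test_map_dimensions(self, rng):
        img = rng.integers(0, 256, (30, 40)).astype(float)
        assert ic.match_template(img, rng.integers(0, 256, (5, 7)).astype(float)
                                 ).shape == (26, 34)

    def test_single_placement_map(self, rng):
        img = rng.integers(0, 256, (6, 6)).astype(float)
        rmap = ic.match_template(img, img)
        assert rmap.shape == (1, 1)
        assert rmap[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_fast_equals_naive_loop(self, rng):
        """The vectorized map equals the explicit double loop, placement by
        placement, on random small instances."""
        for _ in range(25):
            ih, iw = rng.integers(8, 33, 2)
            th = int(rng.integers(2, ih + 1))
            tw = int(rng.integers(2, iw + 1))
            img = rng.integers(0, 256, (ih, iw)).astype(float)
            tpl = rng.integers(0, 256, (th, tw)).astype(float)
            if np.ptp(tpl) == 0:
                continue
            fast = ic.match_template(img, tpl)
            naive = ic.match_template_naive(img, tpl)
            np.testing.assert_allclose(fast, naive, atol=1e-9)

    def test_agrees_with_skimage_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (40, 50)).astype(float)
            tpl = rng.integers(0, 256, (9, 11)).astype(float)
            ours = ic.match_template(img, tpl)
            ref = skimage_match(img, tpl, pad_input=False)
            np.testing.assert_allclose(ours, ref, atol=1e-7)

    def test_values_bounded(self, rng):
        for _ in range(100):
            ih, iw = rng.integers(6, 25, 2)
            img = rng.integers(0, 256, (ih, iw)).astype(float)
            tpl = rng.integers(0, 256, (int(rng.integers(2, 6)),
                                        int(rng.integers(2, 6)))).astype(float)
            if np.ptp(tpl) == 0:
                continue
            rmap = ic.match_template(img, tpl)
            assert rmap.min() >= -1.0 - 1e-9 and rmap.max() <= 1.0 + 1e-9

    def test_illumination_invariance(self, rng):
        """Affine intensity changes of the image leave the map unchanged."""
        img = rng.integers(0, 256, (30, 30)).astype(float)
        tpl = rng.integers(0, 256, (6, 8)).astype(float)
        base = ic.match_template(img, tpl)
        for a, b in [(2.0, 0.0), (0.5, 40.0), (1.7, -20.0)]:
            np.testing.assert_allclose(
                ic.match_template(a * img + b, tpl), base, atol=1e-9)

    def test_self_peak_exactly_one_at_embedding(self, rng):
        tpl = rng.integers(0, 256, (5, 8)).astype(float)
        img = np.full((40, 40), 30.0)
        img[12:17, 20:28] = tpl
        rmap = ic.match_template(img, tpl)
        peak = np.unravel_index(np.argmax(rmap), rmap.shape)
        assert peak == (12, 20)
        assert rmap[peak] == pytest.approx(1.0, abs=1e-9)

    def test_constant_template_raises(self, rng):
        with pytest.raises(DegenerateTemplateError):
            ic.match_template(rng.integers(0, 256, (10, 10)).astype(float),
                              np.ones((3, 3)))
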