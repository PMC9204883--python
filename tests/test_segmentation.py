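"""Segmentation chain: gate oracle, Otsu oracle, morphology, composition."""

import colorsys

import numpy as np
import pytest
from scipy import ndimage as ndi

from truss_seg.segmentation import (
    HSV_PRESETS,
    HsvRange,
    SegmentationConfig,
    hsv_gate,
    morph_clean,
    otsu_threshold,
    segment_truss,
    segmentation_score,
)


def brute_force_gate(image: np.ndarray, r: HsvRange) -> np.ndarray:
    """Per-pixel interval membership via the stdlib hexcone transform."""
    h, w = image.shape[:2]
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            rr, gg, bb = (int(v) / 255.0 for v in image[i, j])
            hh, ss, vv = colorsys.rgb_to_hsv(rr, gg, bb)
            H = round(hh * 360.0 / 2.0) % 180
            S = round(ss * 255.0)
            V = round(vv * 255.0)
            out[i, j] = (
                r.h_lo <= H <= r.h_hi
                and r.s_lo <= S <= r.s_hi
                and r.v_lo <= V <= r.v_hi
            )
    return out


class TestHsvGate:
    def test_pure_red_passes_production_preset(self):
        img = np.zeros((1, 1, 3), np.uint8)
        img[0, 0] = [255, 0, 0]  # H=0, S=255, V=255
        assert hsv_gate(img, HSV_PRESETS["c"])[0, 0]

    def test_pure_blue_fails_production_preset(self):
        img = np.zeros((1, 1, 3), np.uint8)
        img[0, 0] = [0, 0, 255]  # hue 120 on the 0-179 scale
        assert not hsv_gate(img, HSV_PRESETS["c"])[0, 0]

    @pytest.mark.parametrize("preset", sorted(HSV_PRESETS))
    def test_matches_per_pixel_oracle_on_random_image(self, preset, rng):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            hsv_gate(img, HSV_PRESETS[preset]),
            brute_force_gate(img, HSV_PRESETS[preset]),
        )

    def test_out_of_scale_range_rejected(self):
        with pytest.raises(ValueError):
            HsvRange(0, 200, 0, 255, 0, 255)  # hue beyond 179
        with pytest.raises(ValueError):
            HsvRange(30, 0, 0, 255, 0, 255)  # lo > hi


def exhaustive_otsu(gray: np.ndarray) -> int:
    """Argmax of between-class variance by explicit search over 256 levels."""
    hist = np.bincount(gray.ravel(), minlength=256)
    total = gray.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        n0 = hist[: t + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / n0
            mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / n1
            var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_bimodal_split_is_exact(self):
        gray = np.full((10, 10), 50, np.uint8)
        gray.reshape(-1)[:60] = 200
        t, binary = otsu_threshold(gray)
        assert 50 <= t < 200
        np.testing.assert_array_equal(binary, gray == 200)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
            t, binary = otsu_threshold(gray)
            assert t == exhaustive_otsu(gray)
            np.testing.assert_array_equal(binary, gray > t)

    def test_matches_skimage_cross_check(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(10):
            gray = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
            t, _ = otsu_threshold(gray)
            assert t == int(threshold_otsu(gray))

    def test_constant_image_all_background(self):
        gray = np.full((8, 8), 77, np.uint8)
        t, binary = otsu_threshold(gray)
        assert not binary.any()

    def test_empty_and_wrong_dtype_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.empty((0,), np.uint8))
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros((4, 4), np.float64))


class TestMorphClean:
    def test_all_false_fixed_point(self):
        mask = np.zeros((32, 32), bool)
        assert not morph_clean(mask).any()

    def test_rectangle_preserved_up_to_erosion_rim(self):
        mask = np.zeros((40, 40), bool)
        mask[8:30, 10:32] = True
        cfg = SegmentationConfig(min_component_area=0)
        out = morph_clean(mask, cfg)
        # oracle: closing and filling a solid rectangle is the identity,
        # so the result is exactly the 3x3-eroded rectangle
        expected = np.zeros_like(mask)
        expected[9:29, 11:31] = True
        np.testing.assert_array_equal(out, expected)

    def test_interior_holes_filled(self):
        from skimage.draw import disk

        mask = np.zeros((48, 48), bool)
        rr, cc = disk((24, 24), 15)
        mask[rr, cc] = True
        holes = [(20, 22), (26, 27), (24, 18)]
        for r, c in holes:
            mask[r, c] = False
        out = morph_clean(mask, SegmentationConfig(min_component_area=0))
        assert all(out[r, c] for r, c in holes)

    def test_small_components_removed(self):
        mask = np.zeros((64, 64), bool)
        mask[5:8, 5:8] = True  # 9 px -> gone after erosion + area filter
        mask[20:45, 20:45] = True
        out = morph_clean(mask)
        assert not out[:10, :10].any()
        assert out[30, 30]

    def test_output_subset_of_filled_closing(self, rng):
        """Erosion monotonicity: cleanup never adds pixels beyond the
        filled closing of its input."""
        cfg = SegmentationConfig()
        for _ in range(5):
            mask = ndi.binary_dilation(
                rng.random((48, 48)) > 0.97, iterations=2
            )
            out = morph_clean(mask, cfg)
            from truss_seg.segmentation import _ellipse_footprint

            envelope = ndi.binary_fill_holes(
                ndi.binary_closing(mask, structure=_ellipse_footprint(cfg.closing_kernel))
            )
            assert not (out & ~envelope).any()


class TestSegmentTruss:
    def test_recovers_truth_on_clean_scene(self, clean_scene):
        mask = segment_truss(clean_scene.depth_colormap())
        from truss_seg.evaluation import miou

        assert miou(mask, clean_scene.truth) >= 90.0

    def test_all_blue_image_empty_mask(self):
        img = np.zeros((64, 64, 3), np.uint8)
        img[..., 2] = 255
        assert not segment_truss(img).any()

    def test_deterministic(self, clean_scene):
        img = clean_scene.depth_colormap()
        np.testing.assert_array_equal(segment_truss(img), segment_truss(img))

    def test_contained_in_filled_gate_region(self, clean_scene):
        """No truss pixel is reported where the gate was false and no
        morphological fill could reach."""
        from truss_seg.segmentation import _ellipse_footprint, hsv_gate

        cfg = SegmentationConfig()
        img = clean_scene.depth_colormap()
        gate = hsv_gate(img, cfg.hsv_range)
        envelope = ndi.binary_fill_holes(
            ndi.binary_closing(gate, structure=_ellipse_footprint(cfg.closing_kernel))
        )
        mask = segment_truss(img, cfg)
        assert not (mask & ~envelope).any()

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            segment_truss(np.zeros((32, 32), np.uint8))

    def test_score_is_gated_luma(self, clean_scene):
        img = clean_scene.depth_colormap()
        score = segmentation_score(img)
        assert score.shape == img.shape[:2]
        gate = hsv_gate(img, SegmentationConfig().hsv_range)
        assert (score[~gate] == 0).all()
        assert score[gate].min() > 0
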