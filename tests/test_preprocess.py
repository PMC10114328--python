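"""Preprocessing SOP: each step against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fundusdr as f
from fundusdr.preprocess import circular_mask, resize


def brute_bbox(mask):
    """Exhaustive scan for the tightest box covering every 1."""
    coords = [(i, j) for i in range(mask.shape[0]) for j in range(mask.shape[1]) if mask[i, j]]
    if not coords:
        return None
    rows = [c[0] for c in coords]
    cols = [c[1] for c in coords]
    return min(rows), max(rows) + 1, min(cols), max(cols) + 1


class TestGray:
    def test_endpoints(self):
        white = np.full((4, 4, 3), 255, dtype=np.uint8)
        black = np.zeros((4, 4, 3), dtype=np.uint8)
        assert (f.rgb_to_gray(white) == 255).all()
        assert (f.rgb_to_gray(black) == 0).all()

    def test_pure_red_luma(self):
        px = np.array([[[255, 0, 0]]], dtype=np.uint8)
        assert f.rgb_to_gray(px)[0, 0] == 76  # round(0.299 * 255)

    def test_invalid_shape_rejected(self):
        with pytest.raises(f.InvalidInputError):
            f.rgb_to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestClipMask:
    def test_strict_threshold_rule(self):
        gray = np.array([[7, 8]], dtype=np.uint8)
        mask = f.build_clip_mask(gray, tolerance=7)
        assert mask[0, 0] == 0 and mask[0, 1] == 1

    def test_all_zero_gray(self):
        assert f.build_clip_mask(np.zeros((5, 5), dtype=np.uint8), 7).sum() == 0

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 30))
    def test_matches_elementwise_bruteforce(self, seed, tol):
        gray = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        mask = f.build_clip_mask(gray, tol)
        for i in range(16):
            for j in range(16):
                assert mask[i, j] == (1 if gray[i, j] > tol else 0)


class TestBBox:
    def test_block_of_ones(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 2:6] = 1
        assert f.content_bbox(mask) == (3, 7, 2, 6)

    def test_full_and_empty(self):
        assert f.content_bbox(np.ones((4, 6), dtype=np.uint8)) == (0, 4, 0, 6)
        assert f.content_bbox(np.zeros((4, 6), dtype=np.uint8)) is None

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce(self, seed):
        mask = (np.random.default_rng(seed).random((16, 16)) < 0.1).astype(np.uint8)
        assert f.content_bbox(mask) == brute_bbox(mask)


class TestAutocrop:
    def test_removes_black_frame(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[3:7, 3:7] = 200
        out = f.autocrop(img, 7)
        assert out.shape == (4, 4, 3)
        assert (out == img[3:7, 3:7]).all()

    def test_no_border_is_identity(self):
        img = np.full((6, 6, 3), 100, dtype=np.uint8)
        assert (f.autocrop(img, 7) == img).all()

    def test_all_black_returned_unchanged(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        assert (f.autocrop(img, 7) == img).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_content_preserving(self, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        r0, c0 = rng.integers(0, 8, 2)
        img[r0 : r0 + rng.integers(1, 8), c0 : c0 + rng.integers(1, 8)] = rng.integers(
            60, 256, 3
        )
        once = f.autocrop(img, 7)
        twice = f.autocrop(once, 7)
        assert once.shape == twice.shape and (once == twice).all()
        # no above-tolerance pixel is lost
        assert (f.rgb_to_gray(once) > 7).sum() == (f.rgb_to_gray(img) > 7).sum()


class TestCircularCrop:
    def test_mask_counts_match_exhaustive_check(self):
        for side in (6, 7, 16):
            mask = circular_mask(side)
            c = side / 2.0
            expected = sum(
                (i + 0.5 - c) ** 2 + (j + 0.5 - c) ** 2 <= c * c
                for i in range(side)
                for j in range(side)
            )
            assert mask.sum() == expected

    def test_white_square_corners_zeroed_center_kept(self):
        img = np.full((8, 8, 3), 255, dtype=np.uint8)
        out = f.circular_crop(img, 7)
        assert out.shape[0] == out.shape[1]
        assert (out[0, 0] == 0).all() and (out[-1, -1] == 0).all()
        mid = out.shape[0] // 2
        assert (out[mid, mid] == 255).all()

    def test_rect_input_goes_through_square(self):
        img = np.full((4, 6, 3), 255, dtype=np.uint8)
        out = f.circular_crop(img, 7)
        assert out.shape[0] == out.shape[1]

    def test_stable_on_already_circular(self, fundus_sample):
        once = f.circular_crop(f.autocrop(fundus_sample.image, 7), 7)
        twice = f.circular_crop(once, 7)
        # geometry is stable and interior pixels survive a second pass
        assert twice.shape == once.shape
        side = once.shape[0]
        inner = circular_mask(side) & (circular_mask(side + 2)[1:-1, 1:-1])
        assert (once[inner] == twice[inner]).mean() > 0.99

    def test_outside_disc_is_black(self, fundus_sample):
        out = f.circular_crop(f.autocrop(fundus_sample.image, 7), 7)
        outside = ~circular_mask(out.shape[0])
        assert (out[outside] == 0).all()


class TestEqualize:
    def test_two_level_channel_maps_to_extremes(self):
        ch = np.full((20, 20), 100, dtype=np.uint8)
        ch[:5] = 200  # 25% at 200, 75% at 100
        out = f.equalize_channel(ch)
        assert set(np.unique(out)) == {0, 255}
        assert (out[ch == 100] == 0).all() and (out[ch == 200] == 255).all()

    def test_single_level_maps_to_zero(self):
        ch = np.full((8, 8), 77, dtype=np.uint8)
        assert (f.equalize_channel(ch) == 0).all()

    def test_empty_selection_is_bit_identical(self, fundus_sample):
        out = f.equalize_hsv(fundus_sample.image, ())
        assert (out == fundus_sample.image).all()

    def test_shape_preserved(self, fundus_sample):
        out = f.equalize_hsv(fundus_sample.image)
        assert out.shape == fundus_sample.image.shape

    def test_cdf_becomes_linear_on_noise(self, rng):
        """Equalizing a many-level channel flattens its histogram: the
        empirical CDF deviates from linear by <= 2/256 in sup norm."""
        ch = rng.integers(0, 256, (128, 128)).astype(np.uint8)
        ch = (ch * 0.7 + 40).astype(np.uint8)  # compress to a sub-range
        out = f.equalize_channel(ch)
        ecdf = np.cumsum(np.bincount(out.ravel(), minlength=256)) / out.size
        linear = (np.arange(256) + 1) / 256.0
        assert np.abs(ecdf - linear).max() <= 2 / 256

    def test_direct_cdf_oracle(self, rng):
        """T(v) recomputed independently from the definition."""
        ch = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        hist = np.bincount(ch.ravel(), minlength=256)
        cdf = np.cumsum(hist)
        cdf_min = cdf[np.nonzero(hist)[0][0]]
        expected = np.round((cdf - cdf_min) / (ch.size - cdf_min) * 255).astype(int)
        out = f.equalize_channel(ch)
        for v in np.unique(ch):
            assert (out[ch == v] == expected[v]).all()


class TestRunSOP:
    def test_synthetic_bordered_fundus(self, fundus_sample):
        res = f.run_sop(fundus_sample.image, f.SOPConfig(output_side=224))
        assert res.image.shape == (224, 224, 3)
        assert not res.rejected
        assert (res.image[0, 0] == 0).all() and (res.image[-1, -1] == 0).all()
        assert res.steps[0] == "autocrop" and res.steps[-1] == "resize:224"

    def test_all_black_input_rejected_without_crash(self):
        res = f.run_sop(np.zeros((64, 64, 3), dtype=np.uint8), f.SOPConfig(output_side=64))
        assert res.rejected and res.quality_label == "reject"
        assert res.image.shape == (64, 64, 3)

    def test_output_side_respected(self, fundus_sample):
        for side in (32, 64):
            res = f.run_sop(fundus_sample.image, f.SOPConfig(output_side=side))
            assert res.image.shape == (side, side, 3)

    def test_geometry_idempotent(self, fundus_sample):
        cfg = f.SOPConfig(output_side=64, equalize_channels=())
        once = f.run_sop(fundus_sample.image, cfg)
        again = f.run_sop(once.image, cfg)
        assert again.image.shape == once.image.shape
        # crop steps find nothing more to remove: images stay highly similar
        diff = np.abs(once.image.astype(int) - again.image.astype(int))
        assert np.mean(diff) < 3


def test_resize_contract():
    img = np.zeros((10, 20, 3), dtype=np.uint8)
    assert resize(img, 5, 8).shape == (5, 8, 3)
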