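"""LT-CLAHE and dual color-space enhancement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmcformer.enhancement import (ClipParams, clahe_channel,
                                   compute_clip_limit,
                                   default_truncation_bound, enhance_image,
                                   equalization_map, lt_clahe_channel,
                                   redistribute_clipped, rgb_to_lab8,
                                   to_grayscale)
from reference_impl import ref_clahe, ref_redistribute


class TestClipLimit:
    @pytest.mark.parametrize("M,L,norm,expected", [
        (4096, 256, 4, 1036.0),
        (6400, 256, 40, 184.375),
    ])
    def test_formula(self, M, L, norm, expected):
        assert compute_clip_limit(M, L, norm) == pytest.approx(expected)

    def test_large_norm_approaches_uniform_level(self):
        # no clipping headroom left: limit tends to M/L
        assert compute_clip_limit(256, 256, 1e12) == pytest.approx(1.0)

    @pytest.mark.parametrize("M,L,norm", [(100, 256, 4), (0, 8, 4),
                                          (256, 256, 0.0), (256, 256, -1)])
    def test_invalid_parameters(self, M, L, norm):
        with pytest.raises(ValueError):
            compute_clip_limit(M, L, norm)


class TestRedistribution:
    def test_frozen_example(self):
        # L=6, D=4, clip 4: excess 6 from bin 0 fills bins 1..3 in passes
        clip = ClipParams(clip_limit=4.0, D=4)
        h = np.array([10, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(
            redistribute_clipped(h, clip), [4, 2, 2, 2, 0, 0])

    def test_no_excess_is_identity(self):
        clip = ClipParams(clip_limit=10.0, D=5)
        h = np.array([3, 9, 1, 0, 2, 5, 0, 7])
        np.testing.assert_array_equal(redistribute_clipped(h, clip), h)

    def test_saturated_histogram_is_identity(self):
        clip = ClipParams(clip_limit=4.0, D=5)
        h = np.full(8, 4)
        np.testing.assert_array_equal(redistribute_clipped(h, clip), h)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            redistribute_clipped(np.array([]), ClipParams(4.0, 2))

    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([8, 64, 256]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_reference_and_invariants(self, seed, L):
        rng = np.random.default_rng(seed)
        M = L * int(rng.integers(1, 40))
        h = rng.multinomial(M, rng.dirichlet(np.full(L, 0.3)))
        clip = ClipParams.for_tile(M, L, float(rng.uniform(1.1, 60.0)))
        out = redistribute_clipped(h, clip)
        np.testing.assert_array_equal(
            out, ref_redistribute(h, clip.clip_limit, clip.D))
        assert out.sum() == M                                # conservation
        D = clip.D
        clipped = np.minimum(h, int(np.floor(clip.clip_limit)))
        # truncation locality: bins >= D never gain mass
        assert np.all(out[D:] == clipped[D:])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_clipping_ceiling(self, seed):
        rng = np.random.default_rng(seed)
        L = 64
        M = L * int(rng.integers(4, 40))
        h = rng.multinomial(M, rng.dirichlet(np.full(L, 0.3)))
        clip = ClipParams.for_tile(M, L, 4.0)   # ample receiving capacity
        out = redistribute_clipped(h, clip)
        assert out.max() <= int(np.ceil(clip.clip_limit))


class TestEqualizationMap:
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=64))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_transfer_function_monotone(self, counts):
        lut = equalization_map(np.asarray(counts))
        assert np.all(np.diff(lut) >= 0)
        assert lut.min() >= 0 and lut.max() <= len(counts) - 1


class TestTiledEqualization:
    def test_limit_equivalence_with_standard_clahe(self, rng):
        # with D = L, LT-CLAHE must equal the textbook-CLAHE oracle exactly
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        ours = lt_clahe_channel(img, grid=(4, 4), norm_clip_limit=6.0, D=256)
        ref = ref_clahe(img, (4, 4), 6.0)
        np.testing.assert_array_equal(ours, ref)

    def test_clahe_channel_is_lt_with_full_range(self, rng):
        img = rng.integers(0, 256, (64, 48)).astype(np.uint8)
        np.testing.assert_array_equal(
            clahe_channel(img, grid=(2, 2), norm_clip_limit=3.0),
            lt_clahe_channel(img, grid=(2, 2), norm_clip_limit=3.0, D=256))

    def test_truncated_variant_matches_loop_oracle(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        ours = lt_clahe_channel(img, grid=(2, 2), norm_clip_limit=8.0)
        ref = ref_clahe(img, (2, 2), 8.0, D=default_truncation_bound(256))
        np.testing.assert_array_equal(ours, ref)

    def test_two_level_image_matches_tile_centre_mapping(self, rng):
        # at a tile centre only that tile's transfer function applies
        img = (rng.integers(0, 2, (64, 64)) * 200 + 20).astype(np.uint8)
        out = lt_clahe_channel(img, grid=(2, 2), norm_clip_limit=4.0)
        ref = ref_clahe(img, (2, 2), 4.0, D=default_truncation_bound(256))
        np.testing.assert_array_equal(out, ref)
        th = tw = 32
        for i in range(2):
            for j in range(2):
                cy, cx = i * th + th // 2, j * tw + tw // 2
                assert out[cy, cx] == ref[cy, cx]

    def test_constant_channel_stays_constant(self):
        img = np.full((32, 32), 77, dtype=np.uint8)
        out = lt_clahe_channel(img, grid=(2, 2))
        assert np.unique(out).size == 1

    def test_geometry_errors(self):
        with pytest.raises(ValueError):
            lt_clahe_channel(np.zeros((4, 4), dtype=np.uint8), grid=(8, 8))
        with pytest.raises(ValueError):
            lt_clahe_channel(np.zeros((8, 8, 3), dtype=np.uint8))

    def test_non_divisible_sizes_are_padded(self, rng):
        img = rng.integers(0, 256, (50, 46)).astype(np.uint8)
        out = lt_clahe_channel(img, grid=(2, 2))
        assert out.shape == (50, 46)

    def test_determinism(self, rng):
        img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        a = lt_clahe_channel(img, grid=(2, 2))
        b = lt_clahe_channel(img.copy(), grid=(2, 2))
        np.testing.assert_array_equal(a, b)


class TestEnhancePipeline:
    def test_shape_range_and_dtype(self, lesion_image):
        img, _ = lesion_image
        out = enhance_image(img)
        assert out.shape == img.shape and out.dtype == np.uint8

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            enhance_image(np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError):
            enhance_image(np.zeros((32, 32, 3), dtype=np.float32))

    def test_chroma_contrast_increases_on_lesion(self, lesion_image):
        # the point of the method: pale patch vs pink background separate
        # further in the chroma (A/B) channels after enhancement
        img, mask = lesion_image
        out = enhance_image(img)
        bg = ~mask
        before = after = 0.0
        for c in (1, 2):
            lab_in = rgb_to_lab8(img)[..., c].astype(float)
            lab_out = rgb_to_lab8(out)[..., c].astype(float)
            before += abs(lab_in[mask].mean() - lab_in[bg].mean())
            after += abs(lab_out[mask].mean() - lab_out[bg].mean())
        assert after > before

    @pytest.mark.parametrize("px,expected", [
        ((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 100, 100), 100)])
    def test_grayscale_fixed_points(self, px, expected):
        img = np.full((4, 4, 3), px, dtype=np.uint8)
        assert np.all(to_grayscale(img) == expected)

    def test_blend_of_identical_images_is_identity(self):
        a = np.random.default_rng(0).integers(0, 256, (8, 8, 3))
        blend = np.clip(np.rint(0.5 * a + 0.5 * a), 0, 255)
        np.testing.assert_array_equal(blend, a)
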