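import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from distseg.preprocess_tile import (
    PatchGrid,
    PreprocessConfig,
    bilinear_resize,
    clahe,
    downsample_pred,
    extract_patches,
    padded_image,
    plan_tiles,
    stitch,
    tiled_inference,
    upsample_patch,
    znorm,
)


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = clahe(np.full((64, 64), 5.0))
        assert np.unique(out).size == 1

    def test_output_within_8bit_range(self, rng):
        out = clahe(rng.random((100, 80)) * 1000 - 200)
        assert out.min() >= 0 and out.max() <= 255

    def test_reduces_illumination_gradient_spread(self, rng):
        # linear left-to-right gradient plus fixed texture; per-tile means
        # must spread strictly less after equalization
        x = np.outer(np.ones(256), np.linspace(0, 200, 256))
        x += rng.normal(0, 5, x.shape)
        out = clahe(x)
        before = x.reshape(8, 32, 8, 32).mean(axis=(1, 3)).std()
        after = out.reshape(8, 32, 8, 32).mean(axis=(1, 3)).std()
        assert after < before

    def test_agrees_qualitatively_with_skimage(self, rng):
        # independent CLAHE implementation should also flatten the field;
        # both outputs should correlate strongly on the same input
        from skimage import exposure

        x = np.outer(np.ones(128), np.linspace(0, 1, 128)) + rng.normal(
            0, 0.05, (128, 128)
        )
        ours = clahe(x) / 255.0
        theirs = exposure.equalize_adapthist(
            (x - x.min()) / np.ptp(x), kernel_size=16
        )
        assert np.corrcoef(ours.ravel(), theirs.ravel())[0, 1] > 0.95


class TestZnorm:
    def test_two_value_closed_form(self):
        x = np.array([[0.0, 2.0], [0.0, 2.0]])
        np.testing.assert_allclose(znorm(x), [[-1, 1], [-1, 1]])

    def test_idempotent(self, rng):
        x = rng.random((32, 32))
        np.testing.assert_allclose(znorm(znorm(x)), znorm(x), atol=1e-12)

    def test_constant_maps_to_zero(self):
        assert np.all(znorm(np.full((4, 4), 3.0)) == 0)

    def test_moments(self, rng):
        z = znorm(rng.random((50, 60)) * 100)
        assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6


class TestPlanTiles:
    def test_256_square_gives_four_windows(self):
        g = plan_tiles(256, 256)
        assert (g.padded_height, g.padded_width) == (320, 320)
        assert len(g.windows) == 4

    def test_stride_sized_image_single_window(self):
        g = plan_tiles(192, 192)
        assert (g.padded_height, g.padded_width) == (256, 256)
        assert len(g.windows) == 1

    def test_microscope_frame_704x520(self):
        # 704x520 is a common full-frame size; 4 columns x 3 rows
        g = plan_tiles(520, 704)
        rows = len({r for r, _ in g.windows})
        cols = len({c for _, c in g.windows})
        assert (rows, cols) == (3, 4)
        assert len(g.windows) == 12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 1000), st.integers(1, 1000))
    def test_core_regions_partition_padded_image(self, h, w):
        g = plan_tiles(h, w)
        cover = np.zeros((g.padded_height, g.padded_width), dtype=np.int16)
        for r0, r1, c0, c1 in g.core_regions:
            cover[r0:r1, c0:c1] += 1
        assert (cover == 1).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 1000), st.integers(1, 1000))
    def test_cores_respect_window_margins(self, h, w):
        g = plan_tiles(h, w)
        m, p = g.overlap_margin, g.patch_size
        for (wr, wc), (r0, r1, c0, c1) in zip(g.windows, g.core_regions):
            assert wr <= r0 and r1 <= wr + p and wc <= c0 and c1 <= wc + p
            if r0 != 0:
                assert r0 - wr >= m
            if r1 != g.padded_height:
                assert wr + p - r1 >= m


class TestExtractStitch:
    def test_single_window_patch_is_padded_image(self, rng):
        img = rng.random((192, 192))
        g = plan_tiles(192, 192)
        patches = extract_patches(img, g)
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0], padded_image(img, g))

    def test_adjacent_patches_agree_on_overlap(self, rng):
        img = rng.random((300, 500))
        g = plan_tiles(300, 500)
        patches = extract_patches(img, g)
        cols = len({c for _, c in g.windows})
        # horizontally adjacent windows share a strip of width p - stride
        (r0, c0), (r1, c1) = g.windows[0], g.windows[1]
        assert r0 == r1
        shared = c0 + g.patch_size - c1
        np.testing.assert_array_equal(
            patches[0][:, -shared:], patches[1][:, :shared]
        )
        assert len(patches) == len(g.windows)

    def test_identity_round_trip(self, rng):
        img = rng.random((217, 411))
        g = plan_tiles(*img.shape)
        np.testing.assert_array_equal(stitch(extract_patches(img, g), g), img)

    def test_constant_patches_stitch_constant(self):
        g = plan_tiles(300, 300)
        out = stitch([np.full((256, 256), 0.5)] * len(g.windows), g)
        assert out.shape == (300, 300)
        assert np.all(out == 0.5)

    def test_wrong_patch_count_rejected(self, rng):
        g = plan_tiles(300, 300)
        with pytest.raises(ValueError):
            stitch([np.zeros((256, 256))], g)

    def test_conv_oracle_equivalence(self, rng):
        # a 3x3 convolution is translation-equivariant, so core-cropped
        # stitching must reproduce whole-image application exactly
        kernel = rng.normal(size=(3, 3))

        def conv(p):
            return ndimage.convolve(p, kernel, mode="constant")

        img = rng.random((400, 300))
        g = plan_tiles(*img.shape)
        tiled = stitch([conv(p) for p in extract_patches(img, g)], g)
        whole = conv(padded_image(img, g))
        t, _, l, _ = g.pad_spec
        np.testing.assert_allclose(
            tiled, whole[t : t + 400, l : l + 300], atol=1e-9
        )

    def test_tiled_inference_identity_backbone(self, rng):
        img = rng.random((200, 260))
        out = tiled_inference(img, lambda p: p, preprocess=False)
        np.testing.assert_array_equal(out, img)


class TestResampling:
    def test_factor_one_identity(self, rng):
        p = rng.random((16, 16))
        np.testing.assert_array_equal(upsample_patch(p, 1), p)

    def test_constant_preserved_at_any_factor(self):
        out = upsample_patch(np.full((8, 8), 0.3), 4)
        assert out.shape == (32, 32)
        np.testing.assert_allclose(out, 0.3)

    def test_linear_ramp_preserved_in_interior(self):
        # align-corners-off bilinear reproduces a linear function exactly
        # away from the clamped half-pixel border
        ramp = np.outer(np.ones(32), np.arange(32, dtype=float))
        up = upsample_patch(ramp, 4)
        interior = up[8:-8, 8:-8]
        cols = np.arange(128, dtype=float)[8:-8]
        expected = np.outer(np.ones(112), (cols + 0.5) / 4 - 0.5)
        np.testing.assert_allclose(interior, expected, atol=1e-6)

    def test_down_up_round_trip_shape(self, rng):
        p = rng.random((256, 256))
        big = upsample_patch(p, 4)
        assert big.shape == (1024, 1024)
        back = downsample_pred(big, 256)
        assert back.shape == (256, 256)
        # smooth content survives the round trip closely
        smooth = ndimage.gaussian_filter(p, 4)
        back2 = downsample_pred(upsample_patch(smooth, 4), 256)
        assert np.abs(back2 - smooth).max() < 0.01
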