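import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from panelselect import (
    MultichannelImage,
    normalize_arcsinh_z,
    normalize_clip_blur_z,
    normalize_z,
    random_patches,
    read_multichannel,
    stitch_patches,
    tile_patches,
    write_multichannel,
)
from panelselect.images import (
    CellMask,
    ZeroVarianceWarning,
    arcsinh_divisor,
    read_mask,
    write_channel_table,
    write_mask,
)

RECIPES = [normalize_arcsinh_z, normalize_clip_blur_z, normalize_z]


class TestContainer:
    def test_rejects_mismatched_names(self, rng):
        with pytest.raises(ValueError, match="channel names"):
            MultichannelImage(rng.normal(size=(3, 4, 4)), ("A", "B"))

    def test_rejects_duplicate_names(self, rng):
        with pytest.raises(ValueError, match="unique"):
            MultichannelImage(rng.normal(size=(2, 4, 4)), ("A", "A"))

    def test_channel_selection_reorders_by_name(self, small_image):
        sub = small_image.select_channels(["CD20", "CD3"])
        assert sub.channel_names == ("CD20", "CD3")
        np.testing.assert_array_equal(sub.pixels[1], small_image.channel("CD3"))


class TestIO:
    def test_write_read_round_trip_is_bit_exact(self, small_image, tmp_path):
        img32 = MultichannelImage(
            small_image.pixels.astype(np.float32), small_image.channel_names
        )
        path = write_multichannel(img32, tmp_path / "img.ome.tif")
        back = read_multichannel(path)
        assert back.channel_names == img32.channel_names
        np.testing.assert_array_equal(back.pixels, img32.pixels.astype(np.float64))

    def test_sidecar_channel_table(self, small_image, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(
            path, small_image.pixels.astype(np.float32), photometric="minisblack"
        )
        write_channel_table(small_image.channel_names, tmp_path / "plain.channels.csv")
        back = read_multichannel(path)
        assert back.channel_names == small_image.channel_names

    def test_name_count_mismatch_errors(self, small_image, tmp_path):
        path = write_multichannel(small_image, tmp_path / "img.ome.tif")
        with pytest.raises(ValueError, match="channel names"):
            read_multichannel(path, names=["A", "B"])

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_multichannel(tmp_path / "nope.tif")

    def test_degenerate_1x1x1_image(self, tmp_path):
        img = MultichannelImage(np.array([[[3.5]]], dtype=np.float32), ("X",))
        back = read_multichannel(write_multichannel(img, tmp_path / "t.ome.tif"))
        assert back.pixels.shape == (1, 1, 1)
        assert back.pixels[0, 0, 0] == 3.5

    def test_mask_round_trip(self, tmp_path):
        mask = CellMask(np.array([[0, 1], [2, 2]], dtype=np.int32))
        back = read_mask(write_mask(mask, tmp_path / "m.tif"))
        np.testing.assert_array_equal(back.labels, mask.labels)


class TestNormalization:
    @pytest.mark.parametrize("recipe", RECIPES)
    def test_output_is_zero_mean_unit_sd(self, recipe, small_image):
        out = recipe(small_image)
        for c in range(out.n_channels):
            assert abs(out.pixels[c].mean()) < 1e-6
            assert abs(out.pixels[c].std() - 1) < 1e-6

    @pytest.mark.parametrize("recipe", RECIPES)
    def test_refuses_double_normalization(self, recipe, small_image):
        with pytest.raises(ValueError, match="already normalized"):
            recipe(recipe(small_image))

    def test_arcsinh_divisor_floor_at_15(self):
        # 20th percentile of 2 gives 5*2=10, floored to 15
        channel = np.full((10, 10), 2.0)
        assert arcsinh_divisor(channel) == 15.0
        # large percentile dominates the floor
        channel = np.full((10, 10), 10.0)
        assert arcsinh_divisor(channel) == 50.0

    def test_constant_channel_guard_emits_zeros_and_warns(self):
        img = MultichannelImage(np.full((1, 5, 5), 7.0), ("K",))
        with pytest.warns(ZeroVarianceWarning):
            out = normalize_arcsinh_z(img)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_clip_blur_matches_direct_convolution_on_impulse(self):
        # single bright pixel: the blurred channel must equal scipy's
        # reflective Gaussian of the clipped channel, then z-scored
        raw = np.zeros((1, 17, 17))
        raw[0, 8, 8] = 100.0
        img = MultichannelImage(raw, ("imp",))
        out = normalize_clip_blur_z(img)
        clipped = np.clip(raw[0], 0, np.percentile(raw[0][raw[0] > 0], 98))
        ref = gaussian_filter(clipped, sigma=1.5, mode="reflect")
        ref = (ref - ref.mean()) / ref.std()
        np.testing.assert_allclose(out.pixels[0], ref, atol=1e-12)

    def test_all_zero_channel_under_clip_recipe(self):
        img = MultichannelImage(np.zeros((1, 6, 6)), ("Z",))
        with pytest.warns(ZeroVarianceWarning):
            out = normalize_clip_blur_z(img)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_z_known_values_population_sd(self):
        img = MultichannelImage(np.array([[[1.0, 2.0], [3.0, 4.0]]]), ("A",))
        out = normalize_z(img)
        sigma = np.array([1.0, 2, 3, 4]).std()  # population SD
        np.testing.assert_allclose(
            out.pixels[0].ravel(), (np.array([1.0, 2, 3, 4]) - 2.5) / sigma
        )

    def test_z_is_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=(1, 30, 30))
        x = (x - x.mean()) / x.std()
        out = normalize_z(MultichannelImage(x, ("A",)))
        np.testing.assert_allclose(out.pixels, x, atol=1e-9)


class TestPatches:
    def test_full_size_patch_is_the_image(self, small_image):
        (patch,) = random_patches(small_image, 16, 1, seed=0)
        np.testing.assert_array_equal(patch.pixels, small_image.pixels)

    def test_random_patches_deterministic_given_seed(self, small_image):
        a = random_patches(small_image, 5, 8, seed=42)
        b = random_patches(small_image, 5, 8, seed=42)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)

    def test_patch_shape_and_count(self, small_image):
        patches = random_patches(small_image, 7, 10, seed=1)
        assert len(patches) == 10
        assert all(p.pixels.shape == (4, 7, 7) for p in patches)

    def test_oversized_patch_errors(self, small_image):
        with pytest.raises(ValueError, match="exceeds"):
            random_patches(small_image, 17, 1, seed=0)

    def test_tiling_4x4_by_2_gives_4_disjoint_patches(self, rng):
        img = MultichannelImage(rng.normal(size=(1, 4, 4)), ("A",))
        tiles = tile_patches(img, 2)
        assert [pos for _, pos in tiles] == [(0, 0), (0, 2), (2, 0), (2, 2)]

    def test_tiling_5x5_by_2_re_anchors_final_row_col(self, rng):
        img = MultichannelImage(rng.normal(size=(1, 5, 5)), ("A",))
        tiles = tile_patches(img, 2)
        positions = [pos for _, pos in tiles]
        assert len(tiles) == 9
        assert positions == [
            (0, 0), (0, 2), (0, 3),
            (2, 0), (2, 2), (2, 3),
            (3, 0), (3, 2), (3, 3),
        ]

    def test_single_tile_when_size_equals_image(self, small_image):
        tiles = tile_patches(small_image, 16)
        assert len(tiles) == 1 and tiles[0][1] == (0, 0)

    def test_overlap_stitched_as_mean(self):
        a = MultichannelImage(np.full((1, 2, 2), 1.0), ("A",))
        b = MultichannelImage(np.full((1, 2, 2), 3.0), ("A",))
        out = stitch_patches([(a, (0, 0)), (b, (0, 1))], 2, 3)
        np.testing.assert_array_equal(out.pixels[0, :, 1], [2.0, 2.0])

    def test_uncovered_pixels_error_names_gap(self, rng):
        patch = MultichannelImage(rng.normal(size=(1, 2, 2)), ("A",))
        with pytest.raises(ValueError, match="uncovered"):
            stitch_patches([(patch, (0, 0))], 4, 4)

    @settings(deadline=None, max_examples=25)
    @given(
        h=st.integers(3, 24),
        w=st.integers(3, 24),
        size=st.integers(1, 24),
        data=st.integers(0, 2**31 - 1),
    )
    def test_tile_stitch_round_trip_exact(self, h, w, size, data):
        """Tiling then stitching reproduces any image bit for bit."""
        size = min(size, h, w)
        pixels = np.random.default_rng(data).normal(size=(2, h, w))
        img = MultichannelImage(pixels, ("A", "B"))
        out = stitch_patches(tile_patches(img, size), h, w)
        np.testing.assert_array_equal(out.pixels, img.pixels)
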