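import numpy as np
import pytest

from wavelet_oracle import naive_feature_image, window_feature

from residuemap.multiscale import (
    DT1_FEATURES,
    PyramidLevel,
    WaveletPyramid,
    block_variance,
    build_feature_stack,
    decompose_window,
    extract_feature_image,
    fuse_coefficients,
    heterogeneity_profile,
)


def _scalar_pyramid(a, h, v, d):
    lvl = PyramidLevel(*(np.array([[x]], dtype=float) for x in (a, h, v, d)))
    return WaveletPyramid([lvl])


class TestDecomposeWindow:
    @pytest.mark.parametrize("w", [2, 4, 8, 16])
    def test_constant_window_closed_form(self, w):
        m = int(np.log2(w))
        pyr = decompose_window(np.full((w, w), 3.5))
        assert pyr.n_levels == m
        assert np.allclose(pyr.final.approx, 3.5 * 2**m, atol=1e-9)
        for lvl in pyr.levels:
            for det in (lvl.horizontal, lvl.vertical, lvl.diagonal):
                assert np.abs(det).max() < 1e-9

    def test_subimage_shapes_halve_per_level(self):
        pyr = decompose_window(np.random.default_rng(0).random((16, 16)))
        for m, lvl in enumerate(pyr.levels, start=1):
            assert lvl.approx.shape == (16 // 2**m,) * 2

    def test_matches_independent_filter_bank(self, rng):
        # direct convolve-and-downsample oracle, literal db3 taps
        for w in (2, 4, 8):
            win = rng.uniform(-1, 1, size=(w, w))
            assert np.isclose(
                fuse_coefficients(decompose_window(win)),
                window_feature(win),
                atol=1e-10,
            )

    def test_checkerboard_against_oracle(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
        pyr = decompose_window(board)
        a = pyr.final.approx.item()
        assert np.isclose(a, window_feature(board, "approx"), atol=1e-12)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            decompose_window(np.zeros((6, 6)))


class TestFuseCoefficients:
    def test_maxabs_keeps_sign(self):
        assert fuse_coefficients(_scalar_pyramid(10, -12, 3, 1)) == -12

    def test_approx_rule(self):
        assert fuse_coefficients(_scalar_pyramid(10, -12, 3, 1), "approx") == 10

    def test_constant_window_rules_agree(self):
        pyr = decompose_window(np.full((8, 8), 2.0))
        assert np.isclose(fuse_coefficients(pyr), fuse_coefficients(pyr, "approx"))
        assert np.isclose(fuse_coefficients(pyr), 2.0 * 8)

    def test_exhaustive_over_random_windows(self, rng):
        for _ in range(200):
            pyr = decompose_window(rng.normal(size=(4, 4)))
            finals = [
                pyr.final.approx.item(), pyr.final.horizontal.item(),
                pyr.final.vertical.item(), pyr.final.diagonal.item(),
            ]
            assert fuse_coefficients(pyr) == max(finals, key=abs)

    def test_non_scalar_final_level_rejected(self):
        pyr = decompose_window(np.zeros((8, 8)), levels=2)
        with pytest.raises(ValueError, match="1x1"):
            fuse_coefficients(pyr)


class TestExtractFeatureImage:
    @pytest.mark.parametrize("w", [2, 4, 8, 16])
    def test_constant_image_closed_form(self, w):
        m = int(np.log2(w))
        feat = extract_feature_image(np.full((20, 20), 4.0), w)
        assert np.allclose(feat, 4.0 * 2**m, atol=1e-9)

    @pytest.mark.parametrize("rule", ["maxabs", "approx"])
    def test_matches_naive_per_pixel_loop(self, rng, rule):
        image = rng.uniform(0, 255, size=(18, 18))
        for w in (2, 4, 8):
            fast = extract_feature_image(image, w, rule=rule)
            naive = naive_feature_image(image, w, rule)
            assert np.abs(fast - naive).max() < 1e-9

    def test_translation_equivariance_interior(self, rng):
        image = rng.uniform(0, 255, size=(40, 40))
        shifted = np.roll(image, 1, axis=0)
        f = extract_feature_image(image, 4)
        g = extract_feature_image(shifted, 4)
        # away from the padded border a one-pixel shift of the input
        # shifts the feature image by one pixel
        assert np.allclose(g[9:31, 8:32], f[8:30, 8:32], atol=1e-9)

    def test_mean_scale_removes_orthonormal_gain(self):
        feat = extract_feature_image(np.full((16, 16), 10.0), 8, scale="mean")
        assert np.allclose(feat, 10.0, atol=1e-9)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="reflect"):
            extract_feature_image(np.zeros((10, 10)), 64)

    def test_bad_rule_and_scale(self):
        with pytest.raises(ValueError):
            extract_feature_image(np.zeros((8, 8)), 4, rule="sum")
        with pytest.raises(ValueError):
            extract_feature_image(np.zeros((8, 8)), 4, scale="log")


class TestBuildFeatureStack:
    def test_eleven_layer_stack(self, overlap_scene, overlap_stack):
        image, _ = overlap_scene
        assert len(overlap_stack.names) == 11
        assert overlap_stack.names[:4] == image.band_names
        assert "PC1" in overlap_stack.names
        assert {f"B_ms{w}" for w in (2, 4, 8, 16, 32, 64)} <= set(overlap_stack.names)
        assert all(
            layer.shape == image.shape for layer in overlap_stack.layers.values()
        )

    def test_spectral_only_subset(self, overlap_stack):
        sub = overlap_stack.subset(DT1_FEATURES)
        assert sub.names == DT1_FEATURES

    def test_multiscale_layers_standardized(self, overlap_stack):
        for w in (2, 64):
            layer = overlap_stack.layers[f"B_ms{w}"]
            assert abs(layer.mean()) < 1e-9
            assert np.isclose(layer.std(), 1.0)
            assert overlap_stack.provenance[f"B_ms{w}"]["standardized"]

    def test_missing_subset_layer_raises(self, overlap_stack):
        with pytest.raises(KeyError):
            overlap_stack.subset(("B_blue", "B_ms128"))


class TestBlockVariance:
    def test_constant_layer_zero_variance(self):
        grid, overall = block_variance(np.full((20, 20), 3.0), 5)
        assert (grid == 0).all() and overall == 0.0

    def test_twenty_five_blocks(self, rng):
        # scaled-down analogue of splitting a scene into 25 square blocks
        grid, _ = block_variance(rng.random((45, 45)), 9)
        assert grid.shape == (5, 5)

    def test_matches_two_pass_oracle(self, rng):
        layer = rng.normal(size=(12, 12))
        grid, overall = block_variance(layer, 6)
        blk = layer[:6, :6]
        mean = blk.sum() / 36
        expected = ((blk - mean) ** 2).sum() / 36
        assert np.isclose(grid[0, 0], expected, rtol=1e-12)
        assert np.isclose(overall, layer.var(), rtol=1e-12)

    def test_partial_blocks_dropped(self, rng):
        grid, _ = block_variance(rng.random((13, 17)), 5)
        assert grid.shape == (2, 3)

    def test_small_block_rejected(self):
        with pytest.raises(ValueError):
            block_variance(np.zeros((10, 10)), 1)


class TestHeterogeneityProfile:
    def test_variance_attenuates_with_window_size(self, overlap_scene):
        from residuemap.pca import pc1_image

        image, _ = overlap_scene
        prof = heterogeneity_profile(pc1_image(image), windows=(2, 8, 32))
        assert prof[2] > prof[8] > prof[32]
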