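"""Preprocessing pipeline: closed-form examples and brute-force oracles."""

import numpy as np
import pytest

from lesiongan import preprocess as pp
from lesiongan.image import ImageTensor, RANGE_8BIT, RANGE_UNIT


def gray(arr, value_range=RANGE_8BIT):
    return ImageTensor(np.asarray(arr, dtype=float)[:, :, None], value_range, "GRAY")


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

class TestNormalize:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0), (128, 128 / 255)])
    def test_endpoints_and_midpoint(self, value, expected):
        out = pp.normalize01(gray(np.full((4, 4), value)))
        assert out.value_range == (0.0, 1.0)
        np.testing.assert_allclose(out.pixels, expected)

    def test_noop_with_warning_when_already_unit_range(self):
        img = gray(np.full((2, 2), 0.5), RANGE_UNIT)
        with pytest.warns(UserWarning):
            out = pp.normalize01(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)


# ----------------------------------------------------------------------
# bicubic resize
# ----------------------------------------------------------------------

def keys_kernel(s, a=-0.5):
    s = abs(s)
    if s <= 1:
        return (a + 2) * s**3 - (a + 3) * s**2 + 1
    if s < 2:
        return a * s**3 - 5 * a * s**2 + 8 * a * s - 4 * a
    return 0.0


def resize_oracle(img, out_h, out_w):
    """Direct 2-D cubic-convolution summation (clamped borders)."""
    in_h, in_w = img.shape[:2]
    out = np.zeros((out_h, out_w, img.shape[2]))
    for i in range(out_h):
        sy = (i + 0.5) * in_h / out_h - 0.5
        for j in range(out_w):
            sx = (j + 0.5) * in_w / out_w - 0.5
            acc = np.zeros(img.shape[2])
            for dy in range(-1, 3):
                for dx in range(-1, 3):
                    yy = int(np.floor(sy)) + dy
                    xx = int(np.floor(sx)) + dx
                    w = keys_kernel(sy - yy) * keys_kernel(sx - xx)
                    acc += w * img[min(max(yy, 0), in_h - 1), min(max(xx, 0), in_w - 1)]
            out[i, j] = acc
    return out


class TestResizeBicubic:
    def test_constant_preserved_at_any_scale(self):
        img = gray(np.full((6, 7), 0.5), RANGE_UNIT)
        out = pp.resize_bicubic(img, 11, 5)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-12)

    def test_identity_scale(self, rng):
        img = ImageTensor(rng.uniform(0, 1, (8, 8, 3)), RANGE_UNIT, "RGB")
        out = pp.resize_bicubic(img, 8, 8)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_sixteen_source_pixels_influence_interior_output(self, rng):
        """Perturbing any of the 4×4 neighbors (and only those) moves the
        output pixel at a non-grid position."""
        base = rng.uniform(0.2, 0.8, (8, 8, 1))
        img = ImageTensor(base, RANGE_UNIT, "GRAY")
        oi, oj = 5, 5  # interior output pixel for 8→9 upscale
        ref = pp.resize_bicubic(img, 9, 9).pixels[oi, oj, 0]
        sy = (oi + 0.5) * 8 / 9 - 0.5
        sx = (oj + 0.5) * 8 / 9 - 0.5
        neighbors = {
            (int(np.floor(sy)) + dy, int(np.floor(sx)) + dx)
            for dy in range(-1, 3)
            for dx in range(-1, 3)
        }
        assert len(neighbors) == 16
        influential = set()
        for y in range(8):
            for x in range(8):
                bumped = base.copy()
                bumped[y, x, 0] += 0.05
                out = pp.resize_bicubic(ImageTensor(bumped, RANGE_UNIT, "GRAY"), 9, 9)
                if abs(out.pixels[oi, oj, 0] - ref) > 1e-12:
                    influential.add((y, x))
        assert influential == neighbors

    def test_matches_direct_summation_oracle(self, rng):
        img = rng.uniform(0.1, 0.9, (6, 6, 3))
        got = pp.resize_bicubic(ImageTensor(img, RANGE_UNIT, "RGB"), 9, 9).pixels
        np.testing.assert_allclose(got, np.clip(resize_oracle(img, 9, 9), 0, 1), atol=1e-6)

    def test_empty_output_rejected(self, random_rgb):
        with pytest.raises(ValueError):
            pp.resize_bicubic(random_rgb, 0, 5)


# ----------------------------------------------------------------------
# histogram CDF + equalization
# ----------------------------------------------------------------------

class TestHistogramCDF:
    def test_constant_image_single_bin_jump(self):
        h = pp.histogram_cdf(gray(np.full((4, 4), 77)))
        assert h.bin_counts[77] == 16
        assert h.cdf[76] == 0.0 and h.cdf[77] == 1.0

    def test_cdf_terminates_at_one_and_counts_sum(self, rng):
        img = gray(rng.integers(0, 256, (13, 7)))
        h = pp.histogram_cdf(img)
        assert h.cdf[255] == pytest.approx(1.0)
        assert h.bin_counts.sum() == 13 * 7
        assert np.all(np.diff(h.cdf) >= 0)

    def test_four_pixel_example(self):
        h = pp.histogram_cdf(gray([[52, 52], [154, 200]]))
        assert h.cdf[52] == pytest.approx(0.5)
        assert h.cdf[154] == pytest.approx(0.75)
        assert h.cdf[200] == pytest.approx(1.0)


class TestEqualizeHistogram:
    def test_constant_image_unchanged(self):
        img = gray(np.full((5, 5), 90))
        np.testing.assert_array_equal(pp.equalize_histogram(img).pixels, img.pixels)

    def test_two_level_extremes_unchanged(self):
        img = gray([[0, 255], [255, 0]])
        np.testing.assert_array_equal(pp.equalize_histogram(img).pixels, img.pixels)

    def test_four_pixel_cdf_mapping(self):
        out = pp.equalize_histogram(gray([[52, 52], [154, 200]]))
        np.testing.assert_array_equal(out.pixels[:, :, 0], [[0, 0], [128, 255]])

    def test_luminance_equalization_preserves_gray_axis_on_rgb(self, rng):
        # equal RGB channels stay (near) equal: hue is not distorted
        g = rng.integers(40, 200, (12, 12)).astype(float)
        img = ImageTensor(np.stack([g, g, g], axis=2), RANGE_8BIT, "RGB")
        out = pp.equalize_histogram(img)
        spread = out.pixels.max(axis=2) - out.pixels.min(axis=2)
        assert spread.max() <= 3.0

    def test_flattens_two_mode_luminance(self, rng):
        """KS distance to the uniform CDF must not grow under equalization."""
        modes = np.where(rng.random((32, 32)) < 0.5, 60, 80)
        img = gray(modes + rng.integers(-5, 6, (32, 32)))

        def ks_to_uniform(im):
            cdf = pp.histogram_cdf(im).cdf
            uniform = np.arange(1, 257) / 256
            return np.abs(cdf - uniform).max()

        assert ks_to_uniform(pp.equalize_histogram(img)) <= ks_to_uniform(img)


# ----------------------------------------------------------------------
# sharpening
# ----------------------------------------------------------------------

class TestSharpenUSM:
    def test_zero_amount_is_identity(self, random_rgb):
        out = pp.sharpen_usm(random_rgb, sigma=1.0, amount=0.0)
        np.testing.assert_allclose(out.pixels, random_rgb.pixels, atol=1e-12)

    def test_constant_image_unchanged(self):
        img = gray(np.full((9, 9), 0.4), RANGE_UNIT)
        out = pp.sharpen_usm(img, sigma=1.5, amount=2.0)
        np.testing.assert_allclose(out.pixels, 0.4, atol=1e-9)

    def test_step_edge_matches_convolution_oracle(self):
        """Direct truncated-Gaussian convolution with reflect padding."""
        row = np.array([0.0] * 10 + [1.0] * 10)
        img = gray(np.tile(row, (9, 1)), RANGE_UNIT)
        sigma, amount = 1.0, 1.0
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-(x**2) / (2 * sigma**2))
        k /= k.sum()
        padded = np.pad(row, radius, mode="reflect")
        blurred = np.array(
            [np.dot(padded[i : i + 2 * radius + 1], k) for i in range(row.size)]
        )
        expected = np.clip(row + amount * (row - blurred), 0, 1)
        got = pp.sharpen_usm(img, sigma, amount).pixels[4, :, 0]
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestGHPF:
    def test_constant_image_is_dc_only(self):
        img = gray(np.full((16, 16), 0.6), RANGE_UNIT)
        out = pp.ghpf(img, cutoff=0.05, gain=1.0)
        np.testing.assert_allclose(out.pixels, 0.6, atol=1e-9)

    def test_zero_gain_is_identity(self, random_rgb):
        out = pp.ghpf(random_rgb, cutoff=0.05, gain=0.0)
        np.testing.assert_allclose(out.pixels, random_rgb.pixels, atol=1e-12)

    def test_single_cosine_attenuation_matches_transfer(self):
        n, cyc, cutoff = 32, 4, 0.1
        f = cyc / n
        x = np.cos(2 * np.pi * f * np.arange(n))
        img = gray(np.tile(0.5 + 0.1 * x, (n, 1)), RANGE_UNIT)
        h = 1.0 - np.exp(-(f**2) / (2 * cutoff**2))
        expected = 0.5 + 0.1 * (1 + h) * np.tile(x, (n, 1))
        out = pp.ghpf(img, cutoff=cutoff, gain=1.0)
        np.testing.assert_allclose(out.pixels[:, :, 0], expected, atol=1e-6)


class TestCombineSharpen:
    def test_usm_only_weights(self, random_rgb):
        cfg = pp.SharpenConfig(weight_usm=1.0, weight_ghpf=0.0)
        np.testing.assert_allclose(
            pp.combine_sharpen(random_rgb, cfg).pixels,
            pp.sharpen_usm(random_rgb, cfg.usm_sigma, cfg.usm_amount).pixels,
        )

    def test_constant_image_fixed_point(self):
        img = gray(np.full((12, 12), 0.3), RANGE_UNIT)
        out = pp.combine_sharpen(img, pp.SharpenConfig())
        np.testing.assert_allclose(out.pixels, 0.3, atol=1e-9)

    def test_equal_weights_average_branches(self, random_rgb):
        cfg = pp.SharpenConfig(weight_usm=0.5, weight_ghpf=0.5)
        usm = pp.sharpen_usm(random_rgb, cfg.usm_sigma, cfg.usm_amount).pixels
        hp = pp.ghpf(random_rgb, cfg.ghpf_cutoff, cfg.ghpf_gain).pixels
        expected = np.clip(0.5 * usm + 0.5 * hp, 0, 1)
        np.testing.assert_allclose(pp.combine_sharpen(random_rgb, cfg).pixels, expected)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            pp.SharpenConfig(weight_usm=0.0, weight_ghpf=0.0)


# ----------------------------------------------------------------------
# color balance
# ----------------------------------------------------------------------

class TestColorBalanceLab:
    def test_lab_channel_means_hit_targets(self, rng):
        from skimage import color as skcolor

        img = ImageTensor(rng.uniform(0.2, 0.8, (16, 16, 3)), RANGE_UNIT, "RGB")
        means, stds = (55.0, 5.0, -5.0), (10.0, 4.0, 4.0)
        out = pp.color_balance_lab(img, means, stds)
        lab = skcolor.rgb2lab(out.pixels)
        for c in range(3):
            assert abs(lab[:, :, c].mean() - means[c]) < 0.5

    def test_fixed_point_when_stats_already_match(self, rng):
        from skimage import color as skcolor

        img = ImageTensor(rng.uniform(0.3, 0.7, (16, 16, 3)), RANGE_UNIT, "RGB")
        lab = skcolor.rgb2lab(img.pixels)
        means = tuple(lab[:, :, c].mean() for c in range(3))
        stds = tuple(lab[:, :, c].std() for c in range(3))
        out = pp.color_balance_lab(img, means, stds)
        assert np.abs(out.pixels - img.pixels).max() <= 2 / 255

    def test_output_stays_in_declared_range(self, rng):
        img = ImageTensor(rng.uniform(0, 1, (16, 16, 3)), RANGE_UNIT, "RGB")
        out = pp.color_balance_lab(img, (80.0, 30.0, 30.0), (40.0, 30.0, 30.0))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_zero_variance_channel_recentered_not_scaled(self):
        img = ImageTensor(np.full((8, 8, 3), 0.5), RANGE_UNIT, "RGB")
        out = pp.color_balance_lab(img)  # no NaNs, stays in range
        assert np.isfinite(out.pixels).all()


# ----------------------------------------------------------------------
# noise + median filter
# ----------------------------------------------------------------------

class TestAddNoise:
    @pytest.mark.parametrize(
        "spec",
        [
            pp.NoiseSpec("salt_pepper", density=0.0),
            pp.NoiseSpec("gaussian", sigma=0.0),
            pp.NoiseSpec("speckle", sigma=0.0),
        ],
    )
    def test_degenerate_parameters_are_identity(self, random_rgb, spec):
        np.testing.assert_array_equal(pp.add_noise(random_rgb, spec).pixels, random_rgb.pixels)

    def test_salt_pepper_corruption_rate(self):
        img = gray(np.full((100, 100), 0.5), RANGE_UNIT)
        out = pp.add_noise(img, pp.NoiseSpec("salt_pepper", density=0.1, seed=3))
        frac = np.mean(out.pixels != 0.5)
        se = np.sqrt(0.1 * 0.9 / 10000)
        assert abs(frac - 0.1) <= 3 * se

    def test_poisson_mean_preserved(self):
        img = gray(np.full((64, 64), 0.5), RANGE_UNIT)
        out = pp.add_noise(img, pp.NoiseSpec("poisson", photon_budget=255.0, seed=1))
        assert abs(out.pixels.mean() - 0.5) < 0.01
        assert out.pixels.std() > 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            pp.NoiseSpec("uniform")


class TestMedianFilter:
    def test_three_by_three_median_of_1_to_9(self):
        img = gray(np.arange(1, 10, dtype=float).reshape(3, 3), RANGE_8BIT)
        assert pp.median_filter(img, 3).pixels[1, 1, 0] == 5

    def test_impulse_removed(self):
        arr = np.full((9, 9), 0.2)
        arr[4, 4] = 1.0
        out = pp.median_filter(gray(arr, RANGE_UNIT), 3)
        np.testing.assert_allclose(out.pixels, 0.2)

    def test_matches_sort_and_pick_oracle(self, rng):
        arr = rng.uniform(0, 1, (8, 8))
        k = 3
        padded = np.pad(arr, k // 2, mode="symmetric")  # edge-repeating reflection
        expected = np.empty_like(arr)
        for i in range(8):
            for j in range(8):
                win = np.sort(padded[i : i + k, j : j + k].ravel())
                expected[i, j] = win[win.size // 2]
        got = pp.median_filter(gray(arr, RANGE_UNIT), k).pixels[:, :, 0]
        np.testing.assert_array_equal(got, expected)

    def test_idempotent_on_impulse_noise_fixture(self, rng):
        arr = np.full((16, 16), 0.4)
        hits = rng.random((16, 16)) < 0.05
        arr[hits] = 1.0
        img = gray(arr, RANGE_UNIT)
        once = pp.median_filter(img, 3)
        twice = pp.median_filter(once, 3)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_even_window_rejected(self, random_rgb):
        with pytest.raises(ValueError):
            pp.median_filter(random_rgb, 4)


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

class TestPipeline:
    def test_all_stages_disabled_is_resize_only(self, random_rgb):
        cfg = pp.PipelineConfig(
            target_size=(16, 16), equalize=False, sharpen=False,
            color_balance=False, median=False,
        )
        out = pp.preprocess_pipeline(random_rgb, cfg)
        np.testing.assert_array_equal(
            out.pixels, pp.resize_bicubic(random_rgb, 16, 16).pixels
        )

    def test_output_contract(self, random_rgb):
        out = pp.preprocess_pipeline(random_rgb, pp.PipelineConfig(target_size=(32, 32)))
        assert out.shape == (32, 32, 3)
        assert out.value_range == (0.0, 1.0)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_composition_equals_manual_stage_sequence(self, random_rgb):
        cfg = pp.PipelineConfig(target_size=(24, 24))
        manual = pp.resize_bicubic(random_rgb, 24, 24)
        manual = pp.equalize_histogram(manual)
        manual = pp.combine_sharpen(manual, cfg.sharpen_cfg)
        manual = pp.color_balance_lab(manual, cfg.lab_target_means, cfg.lab_target_stds)
        manual = pp.median_filter(manual, cfg.median_k)
        out = pp.preprocess_pipeline(random_rgb, cfg)
        np.testing.assert_array_equal(out.pixels, manual.pixels)

    def test_shape_preserved_by_all_non_resize_stages(self, random_rgb):
        for op in (
            lambda im: pp.equalize_histogram(im),
            lambda im: pp.combine_sharpen(im, pp.SharpenConfig()),
            lambda im: pp.color_balance_lab(im),
            lambda im: pp.median_filter(im, 3),
            lambda im: pp.add_noise(im, pp.NoiseSpec("gaussian", sigma=0.05)),
        ):
            assert op(random_rgb).shape == random_rgb.shape
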