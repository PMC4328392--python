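"""Filter contracts against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fiberlayer.core import CalibratedImage
from fiberlayer.errors import InvalidParameterError
from fiberlayer.preprocess import (
    PreprocessConfig,
    despeckle,
    preprocess,
    subtract_background,
)
from fiberlayer.synthetic import FiberFieldSpec, NoiseSpec, apply_noise, generate_fiber_channel, uniform_mask


def bruteforce_median(pixels: np.ndarray, window: int) -> np.ndarray:
    """Independent per-pixel median with edge replication (nested loops)."""
    h = window // 2
    padded = np.pad(pixels, h, mode="edge")
    out = np.empty_like(pixels, dtype=float)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            out[r, c] = np.median(padded[r : r + window, c : c + window])
    return out


def bruteforce_ball_opening(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a spherical-cap element, via explicit offsets."""
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = dr * dr + dc * dc <= radius * radius
    offs = np.stack([dr[inside], dc[inside]], axis=1)
    heights = np.sqrt(radius * radius - (offs**2).sum(axis=1))
    padded = np.pad(pixels.astype(float), radius, mode="edge")
    rows, cols = pixels.shape

    def erode(img_pad):
        out = np.full((rows, cols), np.inf)
        for (orow, ocol), h in zip(offs, heights):
            view = img_pad[radius + orow : radius + orow + rows, radius + ocol : radius + ocol + cols]
            out = np.minimum(out, view - h)
        return out

    def dilate(img):
        img_pad = np.pad(img, radius, mode="edge")
        out = np.full((rows, cols), -np.inf)
        for (orow, ocol), h in zip(offs, heights):
            view = img_pad[radius - orow : radius - orow + rows, radius - ocol : radius - ocol + cols]
            out = np.maximum(out, view + h)
        return out

    return dilate(erode(padded))


class TestDespeckle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_bruteforce_median(self, seed, window):
        rng = np.random.default_rng(seed)
        img = CalibratedImage(rng.uniform(0, 255, (32, 32)), 7.0)
        out = despeckle(img, window)
        np.testing.assert_allclose(out.pixels, bruteforce_median(img.pixels, window), atol=1e-5)

    def test_single_impulse_removed(self):
        pixels = np.zeros((16, 16))
        pixels[8, 8] = 255.0
        out = despeckle(CalibratedImage(pixels, 7.0))
        assert out.pixels[8, 8] == 0.0
        assert not out.pixels.any()

    def test_constant_image_unchanged(self):
        out = despeckle(CalibratedImage(np.full((16, 16), 11.0), 7.0))
        assert np.all(out.pixels == 11.0)

    @pytest.mark.parametrize("window", [2, 4, 1, -3])
    def test_even_or_small_window_rejected(self, window):
        with pytest.raises(InvalidParameterError):
            despeckle(CalibratedImage(np.zeros((16, 16)), 7.0), window)

    def test_window_must_fit_raster(self):
        with pytest.raises(InvalidParameterError):
            despeckle(CalibratedImage(np.zeros((5, 20)), 7.0), 5)

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float32, (9, 9), elements=st.floats(0, 1000, width=32)))
    def test_non_expansive(self, pixels):
        out = despeckle(CalibratedImage(pixels, 7.0)).pixels
        assert out.min() >= pixels.min() - 1e-4
        assert out.max() <= pixels.max() + 1e-4


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(CalibratedImage(np.full((64, 64), 37.0), 7.0), 3.0)
        assert np.allclose(out.pixels, 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_path_matches_bruteforce_opening(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 50, (48, 48)) + np.linspace(0, 40, 48)[None, :]
        img = CalibratedImage(base, 1.0)
        out = subtract_background(img, 7.0, exact=True)
        expected = np.clip(base - bruteforce_ball_opening(base, 7), 0, None)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-4)

    def test_downsampled_path_close_to_exact(self):
        rr, cc = np.mgrid[0:200, 0:200]
        base = 100 + 0.2 * rr + 0.1 * cc
        base[90:93, :] += 600.0
        img = CalibratedImage(base, 7.0)
        exact = subtract_background(img, 10.0, exact=True).pixels
        approx = subtract_background(img, 10.0, exact=False).pixels
        assert np.abs(exact - approx).max() <= 0.01 * 600.0

    def test_thin_line_retained_under_large_ball(self):
        """A 1-px line on zero background survives a 210 px ball nearly fully."""
        pixels = np.zeros((128, 128))
        pixels[:, 60] = 100.0
        out = subtract_background(CalibratedImage(pixels, 7.0), 30.0)  # 210 px
        assert out.pixels[:, 60].min() >= 0.95 * 100.0

    def test_output_bounded_by_input_and_zero(self, rng):
        base = rng.uniform(0, 200, (80, 80))
        img = CalibratedImage(base, 7.0)
        out = subtract_background(img, 4.0).pixels
        assert np.all(out >= 0.0)
        assert np.all(out <= base + 1e-6)

    def test_subpixel_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            subtract_background(CalibratedImage(np.zeros((32, 32)), 0.01), 30.0)
        with pytest.raises(InvalidParameterError):
            subtract_background(CalibratedImage(np.zeros((32, 32)), 7.0), -1.0)


class TestComposedPreprocessing:
    def test_recovers_clean_fiber_raster_from_speckle_and_gradient(self):
        """Despeckle+rolling-ball recover the clean punctate raster to ≤5 %
        of the fiber amplitude per pixel (impulse + smooth background only)."""
        patch = uniform_mask(420, 7.0)
        spec = FiberFieldSpec(per_layer_density={"GL": 1.0}, seed=21)
        clean, _ = generate_fiber_channel(patch, spec)
        noise = NoiseSpec(gaussian_sd=0.0, speckle_rate=5e-4, impulse_amplitude=4000.0, background=(100.0, 40.0, 25.0))
        noisy = apply_noise(clean, noise, 3)
        out = preprocess(noisy, PreprocessConfig())
        err = np.abs(out.pixels - clean.pixels)
        assert err.max() <= 0.05 * spec.fiber_amplitude

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            PreprocessConfig(despeckle_window=4)
        with pytest.raises(InvalidParameterError):
            PreprocessConfig(ball_radius_um=0.0)
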