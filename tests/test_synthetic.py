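"""Generator contracts: geometry, achieved-density truth, pairs, markers, noise."""

import math

import numpy as np
import pytest

from fiberlayer.coloc import match_markers
from fiberlayer.errors import GenerationFailureError, InvalidGeometryError
from fiberlayer.synthetic import (
    FiberFieldSpec,
    NoiseSpec,
    SectionGeometry,
    apply_noise,
    generate_channel_pair,
    generate_fiber_channel,
    generate_marker_sets,
    generate_section,
    uniform_mask,
)


class TestSectionGeometry:
    def test_mask_has_background_plus_three_layers(self, small_section):
        mask, _ = small_section
        assert sorted(np.unique(mask.labels).tolist()) == [0, 1, 2, 3]

    def test_annulus_pixel_count_matches_closed_form(self, small_section):
        mask, _ = small_section
        res = mask.resolution
        r_gcl, r_epl, r_gl = 250.0, 430.0, 610.0
        expected = {
            "GCL": math.pi * (r_gcl * res) ** 2,
            "EPL": math.pi * ((r_epl * res) ** 2 - (r_gcl * res) ** 2),
            "GL": math.pi * ((r_gl * res) ** 2 - (r_epl * res) ** 2),
        }
        for layer, exp in expected.items():
            assert mask.layer_area_px(layer) == pytest.approx(exp, rel=0.01)

    def test_deterministic_given_seed(self, small_geometry):
        m1, d1 = generate_section(small_geometry, seed=3)
        m2, d2 = generate_section(small_geometry, seed=3)
        assert np.array_equal(m1.labels, m2.labels)
        assert np.array_equal(d1.pixels, d2.pixels)

    def test_nuclei_denser_in_gcl_than_epl(self, small_section):
        mask, dapi = small_section
        frac = {
            layer: np.count_nonzero(dapi.pixels[mask.layer_pixels(layer)])
            / mask.layer_area_px(layer)
            for layer in ("GCL", "EPL")
        }
        assert frac["GCL"] > 3 * frac["EPL"]

    @pytest.mark.parametrize(
        "radii",
        [(430.0, 250.0, 610.0), (250.0, 250.0, 610.0), (-10.0, 100.0, 200.0)],
    )
    def test_bad_radii_rejected(self, radii):
        with pytest.raises(InvalidGeometryError):
            SectionGeometry(layer_radii_um=radii, resolution=1.0)

    def test_geometry_must_fit_raster(self):
        with pytest.raises(InvalidGeometryError):
            SectionGeometry(layer_radii_um=(100.0, 200.0, 300.0), resolution=1.0, image_shape=(400, 400))


class TestFiberChannel:
    def test_truth_equals_independent_pixel_recount(self, small_section):
        """Recounting rendered pixels inside each layer reproduces the truth."""
        mask, _ = small_section
        img, truth = generate_fiber_channel(mask, FiberFieldSpec(seed=5))
        fiber_px = img.pixels > 0
        for layer in mask.layer_names:
            layer_bool = mask.layer_pixels(layer)
            recount = 100.0 * np.count_nonzero(fiber_px & layer_bool) / np.count_nonzero(layer_bool)
            assert recount == pytest.approx(truth.per_layer_true_density[layer], abs=1e-12)
        # noise separability: with no noise applied, signal exists only inside layers
        assert not np.any(fiber_px & (mask.labels == 0))

    def test_achieved_gl_density_within_tolerance(self, small_section):
        mask, _ = small_section
        _, truth = generate_fiber_channel(mask, FiberFieldSpec(seed=5))
        assert 0.0126 <= truth.per_layer_true_density["GL"] <= 0.0154

    def test_doubling_target_doubles_truth(self, small_section):
        mask, _ = small_section
        spec1 = FiberFieldSpec(per_layer_density={"GL": 0.014}, seed=5)
        spec2 = FiberFieldSpec(per_layer_density={"GL": 0.028}, seed=5)
        _, t1 = generate_fiber_channel(mask, spec1)
        _, t2 = generate_fiber_channel(mask, spec2)
        assert t2.per_layer_true_density["GL"] == pytest.approx(
            2 * t1.per_layer_true_density["GL"], rel=0.1
        )

    def test_zero_density_gives_blank_channel(self, small_section):
        mask, _ = small_section
        img, truth = generate_fiber_channel(
            mask, FiberFieldSpec(per_layer_density={"GL": 0.0, "EPL": 0.0, "GCL": 0.0}, seed=1)
        )
        assert not img.pixels.any()
        assert all(v == 0.0 for v in truth.per_layer_true_density.values())

    def test_unreachable_density_names_layer(self, small_section):
        mask, _ = small_section
        with pytest.raises(GenerationFailureError, match="EPL"):
            generate_fiber_channel(mask, FiberFieldSpec(per_layer_density={"EPL": 60.0}, seed=1))

    def test_deterministic_given_seed(self, small_section):
        mask, _ = small_section
        i1, _ = generate_fiber_channel(mask, FiberFieldSpec(seed=9))
        i2, _ = generate_fiber_channel(mask, FiberFieldSpec(seed=9))
        assert np.array_equal(i1.pixels, i2.pixels)


class TestChannelPair:
    def test_full_sharing_no_jitter_gives_identical_rasters(self):
        patch = uniform_mask(200, 2.0)
        spec = FiberFieldSpec(per_layer_density={"GL": 1.0}, seed=4)
        a, b, truth = generate_channel_pair(patch, spec, shared_fraction=1.0, jitter_sd_um=0.0)
        assert np.array_equal(a.pixels, b.pixels)
        assert truth.shared_fiber_fraction == 1.0

    @pytest.mark.parametrize("shared", [0.0, 0.5])
    def test_shared_count_bookkeeping(self, shared):
        patch = uniform_mask(200, 2.0)
        spec = FiberFieldSpec(per_layer_density={"GL": 1.0}, seed=4)
        _, _, truth = generate_channel_pair(patch, spec, shared_fraction=shared)
        n = sum(truth.n_fibers.values())
        assert truth.n_shared_fibers == round(shared * n)
        assert sum(truth.n_fibers_b.values()) == n

    def test_channel_b_density_comparable_to_a(self):
        patch = uniform_mask(300, 2.0)
        spec = FiberFieldSpec(per_layer_density={"GL": 1.0}, seed=8)
        _, _, truth = generate_channel_pair(patch, spec, shared_fraction=0.5)
        assert truth.per_layer_true_density_b["GL"] == pytest.approx(
            truth.per_layer_true_density["GL"], rel=0.3
        )


class TestMarkerSets:
    def test_unambiguous_pairs_match_truth(self):
        a, b, truth = generate_marker_sets((600.0, 600.0), 10, 10, 10, shared_offset_sd_um=1.0, seed=2)
        assert truth.marker_truth == {"n_shared": 10, "n_only_a": 0, "n_only_b": 0}
        assert match_markers(a, b, 12.0).n_colocalized == 10

    def test_no_shared_markers_yield_zero_matches(self):
        a, b, _ = generate_marker_sets((900.0, 900.0), 8, 6, 0, seed=3)
        assert match_markers(a, b, 12.0).n_colocalized == 0

    def test_pair_offset_distance_matches_rayleigh_mean(self):
        """Offsets with per-axis sd 2 μm give mean pair distance ≈ 2.5 μm,
        far below the 12 μm cutoff in ≥ 99% of draws (Monte-Carlo)."""
        sd = 2.0
        dists = []
        for seed in range(40):
            a, b, _ = generate_marker_sets((2000.0, 2000.0), 10, 10, 10, sd, seed=seed)
            res = match_markers(a, b, 12.0)
            dists.extend(d for _, _, d in res.pairs)
        dists = np.asarray(dists)
        assert dists.mean() == pytest.approx(sd * math.sqrt(math.pi / 2), rel=0.1)
        assert np.mean(dists < 12.0) >= 0.99

    def test_region_too_small_fails(self):
        with pytest.raises(GenerationFailureError):
            generate_marker_sets((50.0, 50.0), 30, 30, 0, seed=1)


class TestNoise:
    def test_zero_noise_is_identity(self, small_section):
        mask, _ = small_section
        img, _ = generate_fiber_channel(mask, FiberFieldSpec(seed=2))
        out = apply_noise(img, NoiseSpec.none(), 0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_impulses_are_isolated_single_pixels(self, rng):
        from fiberlayer.core import CalibratedImage

        blank = CalibratedImage(np.zeros((400, 400), dtype=np.float32), 7.0)
        spec = NoiseSpec(gaussian_sd=0.0, speckle_rate=2e-3, impulse_amplitude=100.0, background=(0, 0, 0))
        out = apply_noise(blank, spec, 11)
        hits = out.pixels > 0
        assert hits.sum() == round(2e-3 * blank.pixels.size)
        # no two impulses are 8-adjacent
        padded = np.pad(hits, 1)
        rs, cs = np.nonzero(padded)
        for r, c in zip(rs, cs):
            block = padded[r - 1 : r + 2, c - 1 : c + 2]
            assert block.sum() == 1

    def test_noise_deterministic_and_nonnegative(self, rng):
        from fiberlayer.core import CalibratedImage

        img = CalibratedImage(np.zeros((128, 128), dtype=np.float32), 7.0)
        out1 = apply_noise(img, NoiseSpec(), 5)
        out2 = apply_noise(img, NoiseSpec(), 5)
        assert np.array_equal(out1.pixels, out2.pixels)
        assert out1.pixels.min() >= 0.0
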