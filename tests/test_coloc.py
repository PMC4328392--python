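"""Shift correlation, rotated null, and proximity marker matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fiberlayer.coloc import (
    MarkerSet,
    ShiftCorrelationCurve,
    aggregate_counts,
    coloc_curves,
    coloc_test,
    match_markers,
    rotated_control,
    shift_correlation,
)
from fiberlayer.errors import (
    DegreesOfFreedomError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from fiberlayer.preprocess import preprocess
from fiberlayer.synthetic import FiberFieldSpec, NoiseSpec, generate_channel_pair, uniform_mask


class TestShiftCorrelation:
    def test_self_correlation_peaks_at_zero_with_r_one(self, rng):
        a = rng.normal(0, 1, (100, 100))
        curve = shift_correlation(a, a, max_shift=10)
        assert curve.peak_dx == 0
        assert curve.peak_r == pytest.approx(1.0)

    @pytest.mark.parametrize("shift", range(-10, 11))
    def test_recovers_applied_translation_exactly(self, shift):
        """b = a rolled by +s columns peaks at dx = −s (sign convention)."""
        a = np.random.default_rng(3).normal(0, 1, (96, 96))
        b = np.roll(a, shift, axis=1)
        curve = shift_correlation(a, b, max_shift=15)
        assert curve.peak_dx == -shift

    def test_vertical_axis_equivalent(self, rng):
        a = rng.normal(0, 1, (96, 96))
        b = np.roll(a, 4, axis=0)
        curve = shift_correlation(a, b, max_shift=10, axis=0)
        assert curve.peak_dx == -4

    def test_independent_noise_stays_near_zero(self, rng):
        a = rng.normal(0, 1, (300, 300))
        b = rng.normal(0, 1, (300, 300))
        curve = shift_correlation(a, b, max_shift=20)
        assert np.abs(curve.r).max() < 0.02

    def test_r_values_bounded(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        b = rng.uniform(0, 1, (64, 64))
        curve = shift_correlation(a, b, max_shift=12)
        assert np.all(curve.r <= 1.0) and np.all(curve.r >= -1.0)

    def test_constant_raster_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            shift_correlation(np.ones((32, 32)), np.random.default_rng(0).normal(size=(32, 32)), 5)

    def test_shape_mismatch_and_bad_shift_rejected(self, rng):
        a = rng.normal(size=(32, 32))
        with pytest.raises(InvalidParameterError):
            shift_correlation(a, rng.normal(size=(32, 16)), 5)
        with pytest.raises(InvalidParameterError):
            shift_correlation(a, a, max_shift=16)


class TestRotatedControl:
    def test_rotation_invariant_raster_keeps_r_one(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = ((rr - 31.5) ** 2 + (cc - 31.5) ** 2 <= 400).astype(float)
        curve = rotated_control(disc, disc, max_shift=8)
        assert curve.r[np.flatnonzero(curve.dx == 0)[0]] == pytest.approx(1.0)

    def test_control_destroys_true_correspondence(self):
        patch = uniform_mask(420, 7.0)
        spec = FiberFieldSpec(per_layer_density={"GL": 1.5}, seed=31)
        a, b, _ = generate_channel_pair(patch, spec, 0.8, noise=NoiseSpec())
        pa, pb = preprocess(a).pixels, preprocess(b).pixels
        curve = coloc_curves(pa, pb, max_shift=30)
        assert curve.peak_r > 0.2
        assert curve.control_peak_r < 0.1
        assert abs(curve.peak_dx) <= 1

    def test_non_square_raster_rejected(self, rng):
        a = rng.normal(size=(32, 40))
        with pytest.raises(InvalidParameterError):
            rotated_control(a, a, 5)


class TestColocTest:
    @staticmethod
    def curve(dx, r, control):
        return ShiftCorrelationCurve(dx=np.asarray(dx), r=np.asarray(r, float), control_r=np.asarray(control, float))

    def test_identical_test_and_control_give_t_zero_p_one(self):
        curves = [self.curve([-1, 0, 1], [0.1, 0.5, 0.1], [0.1, 0.5, 0.1]) for _ in range(4)]
        rep = coloc_test(curves)
        assert rep.t_stat == 0.0
        assert rep.p_value == 1.0

    def test_constant_nonzero_difference_flagged_degenerate(self):
        curves = [self.curve([-1, 0, 1], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]) for _ in range(3)]
        rep = coloc_test(curves)
        assert rep.degenerate
        assert rep.p_value <= np.finfo(float).tiny

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(DegreesOfFreedomError):
            coloc_test([self.curve([0], [1.0], [0.0])])


class TestMatchMarkers:
    def test_pair_within_cutoff_matches(self):
        a = MarkerSet([[0.0, 0.0]], "A")
        b = MarkerSet([[5.0, 0.0]], "B")
        assert match_markers(a, b, 12.0).n_colocalized == 1

    def test_pair_beyond_cutoff_does_not(self):
        a = MarkerSet([[0.0, 0.0]], "A")
        b = MarkerSet([[13.0, 0.0]], "B")
        res = match_markers(a, b, 12.0)
        assert res.n_colocalized == 0
        assert (res.unmatched_a, res.unmatched_b) == (1, 1)

    def test_globally_closest_pair_wins(self):
        a = MarkerSet([[0.0, 0.0], [10.0, 0.0]], "A")
        b = MarkerSet([[4.0, 0.0]], "B")
        res = match_markers(a, b, 12.0)
        assert res.pairs == [(0, 0, pytest.approx(4.0))]
        assert res.ambiguous  # two candidate partners within the cutoff

    def test_empty_sets_allowed(self):
        res = match_markers(MarkerSet(np.empty((0, 2))), MarkerSet(np.empty((0, 2))))
        assert res.n_colocalized == 0

    def test_symmetric_in_argument_order(self, rng):
        a = MarkerSet(rng.uniform(0, 300, (25, 2)), "A")
        b = MarkerSet(rng.uniform(0, 300, (20, 2)), "B")
        ab = match_markers(a, b, 12.0)
        ba = match_markers(b, a, 12.0)
        assert ab.n_colocalized == ba.n_colocalized
        assert sorted((i, j) for i, j, _ in ab.pairs) == sorted((j, i) for i, j, _ in ba.pairs)

    def test_greedy_equals_hungarian_on_unambiguous_sets(self):
        """On well-separated truth, greedy matching equals the optimal
        assignment (scipy Hungarian oracle restricted to the cutoff)."""
        from fiberlayer.synthetic import generate_marker_sets

        for seed in range(5):
            a, b, truth = generate_marker_sets((900.0, 900.0), 18, 15, 9, 2.0, seed=seed)
            greedy = match_markers(a, b, 12.0)
            big = 1e9
            cost = np.sqrt(((a.points[:, None] - b.points[None, :]) ** 2).sum(-1))
            cost = np.where(cost <= 12.0, cost, big)
            ri, ci = linear_sum_assignment(cost)
            optimal = int(np.sum(cost[ri, ci] < big))
            assert greedy.n_colocalized == optimal == truth.marker_truth["n_shared"]

    def test_cutoff_robustness_on_unambiguous_truth(self):
        from fiberlayer.synthetic import generate_marker_sets

        a, b, truth = generate_marker_sets((900.0, 900.0), 20, 16, 10, 2.0, seed=9)
        counts = {cut: match_markers(a, b, cut).n_colocalized for cut in (10.0, 11.0, 12.0, 13.0, 14.0)}
        assert set(counts.values()) == {truth.marker_truth["n_shared"]}


class TestAggregateCounts:
    @staticmethod
    def result(n_coloc, total_a, total_b):
        from fiberlayer.coloc import MatchResult

        return MatchResult(
            pairs=[], n_colocalized=n_coloc, unmatched_a=total_a - n_coloc, unmatched_b=total_b - n_coloc
        )

    def test_mean_and_sd_across_replicates(self):
        summary = aggregate_counts([self.result(c, c, c) for c in (300, 303, 306)])
        assert summary.mean_colocalized == pytest.approx(303.0)
        assert summary.sd_colocalized == pytest.approx(3.0)

    def test_single_replicate_reports_no_sd(self):
        summary = aggregate_counts([self.result(5, 10, 8)])
        assert summary.sd_colocalized is None
        assert summary.mean_total_a == 10.0

    def test_equal_replicates_have_zero_sd(self):
        summary = aggregate_counts([self.result(4, 9, 9)] * 3)
        assert summary.sd_colocalized == 0.0
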