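"""Event detection: temporal filter, spatial clustering, ATS, surrogate, peaks."""

import numpy as np
import pytest

from urgepfm import events, mespfm, synthgen
from urgepfm.events import ATSeries, SurrogateResult


class TestTemporalMaxFilter:
    def test_spike_spreads_to_neighbours(self):
        x = np.zeros((1, 12))
        x[0, 5] = -0.1
        f = events.temporal_max_filter(x)
        assert np.all(f[0, [4, 5, 6]] == -0.1)
        assert np.all(f[0, [0, 1, 2, 3, 7, 8, 9, 10, 11]] == 0)

    def test_zeros_stay_zero(self):
        assert np.all(events.temporal_max_filter(np.zeros((3, 7))) == 0)

    def test_sign_of_dominant_value_kept(self):
        x = np.array([[0.0, -1.0, 2.0, 0.0]])
        f = events.temporal_max_filter(x)
        # both neighbours take +2 (largest magnitude, sign retained)
        assert f[0, 1] == 2.0
        assert f[0, 2] == 2.0
        assert f[0, 3] == 2.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            events.temporal_max_filter(np.zeros((1, 5)), window=4)

    def test_double_application_widens_by_one_sample(self):
        """Isolated spike: re-filtering extends support one further sample
        each side without changing magnitudes."""
        x = np.zeros((1, 15))
        x[0, 7] = -0.3
        once = events.temporal_max_filter(x)
        twice = events.temporal_max_filter(once)
        assert set(np.flatnonzero(once[0])) == {6, 7, 8}
        assert set(np.flatnonzero(twice[0])) == {5, 6, 7, 8, 9}
        assert np.all(twice[0, 5:10] == -0.3)


class TestSpatialClusterMask:
    def _volume_with_blob(self, n_voxels):
        vol = np.zeros((6, 6, 3, 1))
        flat = np.argwhere(np.ones((6, 6, 3)))
        # face-connected straight segment along x then wrap to next row
        count = 0
        for x in range(6):
            for y in range(6):
                if count < n_voxels and y < 2:
                    vol[x, y, 0, 0] = -1.0
                    count += 1
        return vol

    def test_isolated_voxel_removed(self):
        vol = np.zeros((5, 5, 3, 2))
        vol[2, 2, 1, 0] = -1.0
        mask, masked = events.spatial_cluster_mask(vol, vol, min_size=10)
        assert not mask.any()
        assert not masked.any()

    @pytest.mark.parametrize("n,survives", [(10, True), (9, False)])
    def test_minimum_cluster_size_strict(self, n, survives):
        vol = self._volume_with_blob(n)
        mask, _ = events.spatial_cluster_mask(vol, vol, min_size=10)
        assert mask.any() == survives

    def test_mask_applied_to_original_values(self):
        filtered = self._volume_with_blob(12)
        original = 0.5 * filtered
        _, masked = events.spatial_cluster_mask(filtered, original, min_size=10)
        assert masked.min() == -0.5

    def test_raising_min_size_never_adds_voxels(self, rng):
        vol = (rng.random((8, 8, 4, 5)) < 0.3) * -1.0
        masks = [
            events.spatial_cluster_mask(vol, vol, min_size=m)[0]
            for m in (1, 5, 10, 20)
        ]
        for small, large in zip(masks, masks[1:]):
            assert not np.any(large & ~small)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            events.spatial_cluster_mask(np.zeros((2, 2, 2, 1)), np.zeros((2, 2, 2, 1)), min_size=0)
        with pytest.raises(ValueError):
            events.spatial_cluster_mask(
                np.zeros((2, 2, 2, 1)), np.zeros((2, 2, 2, 1)), connectivity=7
            )


class TestComputeATS:
    def test_nonnegative_values_give_zero_counts(self):
        assert np.all(events.compute_ats(np.abs(np.random.rand(4, 4, 2, 6))).counts == 0)

    def test_single_negative_voxel(self):
        x = np.zeros((3, 3, 1, 10))
        x[1, 1, 0, 7] = -0.2
        counts = events.compute_ats(x).counts
        assert counts[7] == 1 and counts.sum() == 1

    def test_matches_bruteforce_tally(self, rng):
        x = rng.normal(size=(4, 3, 2, 15))
        counts = events.compute_ats(x).counts
        oracle = [
            sum(
                1
                for i in range(4)
                for j in range(3)
                for k in range(2)
                if x[i, j, k, t] < 0
            )
            for t in range(15)
        ]
        np.testing.assert_array_equal(counts, oracle)


@pytest.fixture(scope="module")
def tiny_trimmed(schedule):
    truth = synthgen.make_ground_truth(
        grid=(3, 3, 2), n_rois=1, events_per_roi=1, amplitude=-0.5,
        noise_sd_pct=0.4, seed=4, roi_size=(2, 2, 1),
    )
    series = synthgen.simulate_multiecho_run(schedule, truth, seed=4)
    trimmed, _ = events.trim_to_experimental(series, schedule)
    return trimmed


class TestSurrogate:
    def test_same_seed_reproduces_threshold(self, tiny_trimmed):
        s1 = events.surrogate_threshold(tiny_trimmed, seed=3)
        s2 = events.surrogate_threshold(tiny_trimmed, seed=3)
        np.testing.assert_array_equal(s1.permutation, s2.permutation)
        assert s1.threshold == s2.threshold

    def test_permutation_is_bijection_preserving_values(self, tiny_trimmed):
        s = events.surrogate_threshold(tiny_trimmed, seed=1)
        assert sorted(s.permutation) == list(range(tiny_trimmed.n_timepoints))

    def test_trim_removes_random_pads(self, schedule):
        truth = synthgen.make_ground_truth(
            grid=(3, 3, 2), n_rois=1, events_per_roi=1, amplitude=0.0, seed=0,
            roi_size=(2, 2, 1),
        )
        series = synthgen.simulate_multiecho_run(schedule, truth, seed=0)
        trimmed, keep = events.trim_to_experimental(series, schedule)
        times = series.volume_times_s()[keep]
        assert times.min() >= 30.0 and times.max() < 390.0
        assert trimmed.n_timepoints == 200


class TestSelectROIPeaks:
    def _fake_surrogate(self, grid, T, median_counts=0):
        masked = np.zeros(grid + (T,))
        if median_counts:
            masked[..., :] = 0.0
        ats = ATSeries(counts=np.zeros(T, int), threshold=0.0)
        return SurrogateResult(
            permutation=np.arange(T), seed=0, ats=ats, threshold=0.0,
            masked_decon=masked,
        )

    def test_empty_roi_rejected(self):
        grid, T = (4, 4, 2), 20
        surr = self._fake_surrogate(grid, T)
        with pytest.raises(ValueError):
            events.select_roi_peaks(np.zeros(grid + (T,)), np.zeros(grid, bool), surr)

    def test_subthreshold_counts_give_empty_event_set(self):
        grid, T = (4, 4, 2), 20
        surr = self._fake_surrogate(grid, T)
        roi = np.ones(grid, bool)
        ev = events.select_roi_peaks(np.zeros(grid + (T,)), roi, surr)
        assert len(ev) == 0

    def test_plateau_resolves_to_midpoint(self):
        grid, T = (4, 4, 1), 21
        masked = np.zeros(grid + (T,))
        # equal supra-threshold counts at t = 8, 9, 10, 11 (even plateau)
        masked[:2, :2, 0, 8:12] = -1.0
        surr = self._fake_surrogate(grid, T)
        ev = events.select_roi_peaks(masked, np.ones(grid, bool), surr)
        assert list(ev.timepoints) == [9]  # earlier middle sample

    def test_peak_maps_carry_estimates(self):
        grid, T = (3, 3, 1), 15
        masked = np.zeros(grid + (T,))
        masked[0, 0, 0, 5] = -0.7
        masked[1, 1, 0, 5] = -0.2
        surr = self._fake_surrogate(grid, T)
        ev = events.select_roi_peaks(masked, np.ones(grid, bool), surr)
        assert list(ev.timepoints) == [5]
        assert ev.maps[0][0, 0, 0] == -0.7

    def test_segment_peaks_tie_break(self):
        counts = np.array([0, 3, 3, 0, 0, 2, 5, 5, 5, 1, 0])
        peaks = events._segment_peaks(counts, 0.5)
        # first segment: even plateau (1, 2) -> earlier sample 1
        # second segment: plateau (6, 7, 8) -> middle 7
        assert peaks == [1, 7]


class TestEndToEndDetection:
    def test_planted_events_detected_and_null_quiet(self, schedule):
        truth = synthgen.make_ground_truth(
            grid=(6, 6, 3), n_rois=1, events_per_roi=3, amplitude=-1.0,
            noise_sd_pct=0.4, seed=8, roi_size=(3, 3, 2),
        )
        series = synthgen.simulate_multiecho_run(schedule, truth, seed=8)
        roi = truth.roi_labels == 1
        ev, decon, surr, keep = events.detect_events(series, schedule, roi, seed=8)
        planted = truth.event_onsets[1] - keep[0]
        hits = sum(
            any(abs(int(p) - int(o)) <= 1 for p in ev.timepoints) for o in planted
        )
        assert hits >= 2  # at least 2 of 3 planted events found
        # event maps are negative (positive BOLD) in the ROI at the peak
        for i, t in enumerate(ev.timepoints):
            if any(abs(int(t) - int(o)) <= 1 for o in planted):
                assert ev.maps[i][roi].min() < 0
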