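"""Spike detection, threshold fitting, active-period detection, occurrence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neodepth as nd
from neodepth.events import merge_and_filter_intervals
from neodepth.preprocess import InvalidParameterError, filter_array
from neodepth.synth import _spike_kernel

from helpers import brute_negative_peaks


def _rec(x, fs):
    return nd.TimeSeriesRecording(np.atleast_2d(x), fs, ["ch0"])


class TestDetectMua:
    fs = 20000.0

    def _noise(self, seed, dur_s=5.0):
        rng = np.random.default_rng(seed)
        return filter_array(rng.standard_normal(int(dur_s * self.fs)), 500, 5000, self.fs)

    def test_injected_spikes_recovered_with_timing(self):
        x = self._noise(0)
        sd = x.std()
        k = _spike_kernel(self.fs)
        rng = np.random.default_rng(1)
        onsets = np.sort(rng.choice(np.arange(20000, len(x) - 20000, 4000), 15, replace=False))
        for t in onsets:
            x[t: t + len(k)] += 8 * sd * k
        peak_times = (onsets + np.argmin(k)) / self.fs
        train = nd.detect_mua(_rec(x, self.fs))[0]
        hits = [np.min(np.abs(train.times_s - pt)) < 0.001 for pt in peak_times]
        assert np.mean(hits) >= 0.95

    def test_subthreshold_deflection_ignored(self):
        x = self._noise(2)
        k = _spike_kernel(self.fs)
        t0 = len(x) // 2
        x[t0 - 200: t0 + 200] = 0.0  # quiet region: deflection height is exact
        x[t0: t0 + len(k)] += 4.9 * x.std() * k
        train = nd.detect_mua(_rec(x, self.fs))[0]
        assert not np.any(np.abs(train.times_s - (t0 + np.argmin(k)) / self.fs) < 0.001)

    def test_positive_deflections_not_detected(self):
        x = self._noise(3)
        sd = x.std()
        k = _spike_kernel(self.fs)
        t0 = len(x) // 3
        x[t0: t0 + len(k)] -= 8 * sd * k  # flipped: positive-going
        train = nd.detect_mua(_rec(x, self.fs))[0]
        assert not np.any(np.abs(train.times_s - (t0 + np.argmin(k)) / self.fs) < 0.001)

    def test_matches_brute_force_prominence_scan(self):
        rng = np.random.default_rng(4)
        x = filter_array(rng.standard_normal(10000), 500, 5000, self.fs)
        sd = x.std()
        k = _spike_kernel(self.fs)
        for t in (1500, 4000, 7800):
            x[t: t + len(k)] += 7 * sd * k
        got = np.round(nd.detect_mua(_rec(x, self.fs))[0].times_s * self.fs).astype(int)
        expected = brute_negative_peaks(x, k_sd=5.0)
        assert list(got) == expected

    def test_constant_channel_yields_empty_train(self):
        train = nd.detect_mua(_rec(np.zeros(1000), self.fs))[0]
        assert train.n_spikes == 0


class TestFiringRate:
    def _train(self, times):
        return nd.SpikeTrain(channel="c", times_s=np.asarray(times, float), threshold_used_uv=1.0)

    def test_count_over_duration(self):
        train = self._train(np.linspace(0.1, 4.9, 10))
        assert nd.firing_rate(train, [(0.0, 5.0)])[0] == pytest.approx(2.0)

    def test_empty_train_rate_zero(self):
        train = nd.SpikeTrain(channel="c", times_s=np.zeros(0), threshold_used_uv=1.0)
        assert nd.firing_rate(train, [(0.0, 2.0)])[0] == 0.0

    def test_union_mode_pools_intervals(self):
        train = self._train([0.5, 1.5, 10.5])
        rate = nd.firing_rate(train, [(0.0, 2.0), (10.0, 11.0)], union=True)
        assert rate == pytest.approx(1.0)

    def test_zero_length_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            nd.firing_rate(self._train([0.1]), [(1.0, 1.0)])

    def test_within_burst_rate_matches_generator(self, neonatal_session):
        params, rec, truth = neonatal_session
        train = nd.SpikeTrain(
            channel="PFC1", times_s=truth.spike_times["PFC1"], threshold_used_uv=0.0
        )
        rate = nd.firing_rate(train, [tuple(iv) for iv in truth.event_intervals()], union=True)
        assert rate == pytest.approx(params.spike_rate_hz, rel=0.2)


class TestDetectionThreshold:
    def test_pure_noise_threshold_tracks_rms_statistics(self, rng):
        x = filter_array(rng.standard_normal(300000), 1, 100, 1000.0) * 10
        thr = nd.fit_detection_threshold(_rec(x, 1000.0))
        from neodepth.events import rms_timecourse

        rms, _, _ = rms_timecourse(filter_array(x, 1, 100, 1000.0), 1000.0)
        assert abs(thr.gaussian_mu - rms.mean()) < 0.1 * rms.mean()
        assert thr.threshold_value == pytest.approx(
            thr.gaussian_mu + 3.5 * thr.gaussian_sigma
        )

    def test_threshold_separates_noise_floor_from_bursts(self, neonatal_session):
        _, rec, truth = neonatal_session
        thr = nd.fit_detection_threshold(rec)
        x = filter_array(rec.data[0], 1, 100, 1000.0)
        silent_rms = np.sqrt(
            np.mean(x[: int(truth.events[0].start_s * 1000)] ** 2)
        )
        burst = truth.events[int(np.argmax([e.snr for e in truth.events]))]
        burst_rms = np.sqrt(
            np.mean(x[int(burst.start_s * 1000): int(burst.stop_s * 1000)] ** 2)
        )
        assert silent_rms < thr.threshold_value < burst_rms

    def test_scaling_homogeneity(self, neonatal_session):
        _, rec, _ = neonatal_session
        thr1 = nd.fit_detection_threshold(rec)
        thr2 = nd.fit_detection_threshold(rec.with_data(rec.data * 2.0))
        assert thr2.threshold_value == pytest.approx(2.0 * thr1.threshold_value, rel=1e-3)

    def test_constant_trace_has_no_noise_floor(self):
        with pytest.raises(InvalidParameterError):
            nd.fit_detection_threshold(_rec(np.ones(200000), 1000.0))


class TestMergeAndDurationRules:
    def test_gap_shorter_than_200ms_merges(self):
        assert merge_and_filter_intervals([(0.0, 2.0), (2.15, 4.0)]) == [(0.0, 4.0)]

    def test_gap_of_exactly_200ms_not_merged(self):
        out = merge_and_filter_intervals([(0.0, 2.0), (2.2, 4.0)])
        assert out == [(0.0, 2.0), (2.2, 4.0)]

    def test_duration_rule_strictly_greater_than_one_second(self):
        assert merge_and_filter_intervals([(0.0, 0.9)]) == []
        assert merge_and_filter_intervals([(0.0, 1.0)]) == []
        assert merge_and_filter_intervals([(0.0, 1.2)]) == [(0.0, 1.2)]

    def test_order_stability(self, rng):
        iv = [(float(a), float(a) + 1.5) for a in rng.uniform(0, 100, 20)]
        shuffled = list(iv)
        rng.shuffle(shuffled)
        assert merge_and_filter_intervals(iv) == merge_and_filter_intervals(shuffled)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 100.0, allow_nan=False),
                st.floats(0.01, 5.0, allow_nan=False),
            ),
            max_size=15,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_output_invariants_hold_for_arbitrary_candidates(self, items):
        intervals = [(a, a + d) for a, d in items]
        out = merge_and_filter_intervals(intervals)
        assert out == sorted(out)
        assert all(b - a > 1.0 for a, b in out)
        # surviving events respect the merge gap between each other
        assert all(b[0] - a[1] >= 0.2 for a, b in zip(out, out[1:]))
        assert out == merge_and_filter_intervals(list(reversed(intervals)))


class TestDetectActivePeriods:
    def _threshold(self, value):
        return nd.DetectionThreshold(
            rms_window_s=0.2,
            rms_overlap=0.5,
            band_hz=(1.0, 100.0),
            histogram_bins=100,
            gaussian_mu=value / 2,
            gaussian_sigma=value / 7,
            k_sigma=3.5,
            threshold_value=value / 2 + 3.5 * value / 7,
        )

    def _burst_trace(self, intervals, fs=1000.0, dur=30.0, amp=10.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(dur * fs)) * 0.5
        for a, b in intervals:
            sl = slice(int(a * fs), int(b * fs))
            x[sl] += nd.band_noise(sl.stop - sl.start, fs, 4, 30, rng) * amp
        return _rec(x, fs)

    def test_subthreshold_trace_gives_empty_list(self):
        rec = self._burst_trace([])
        thr = self._threshold(5.0)
        assert nd.detect_active_periods(rec, thr) == []
        assert nd.occurrence_timecourse([], rec.duration_s)[0] == 0.0

    def test_close_bursts_merge_into_one_event(self):
        rec = self._burst_trace([(10.0, 12.0), (12.15, 14.0)])
        evs = nd.detect_active_periods(rec, self._threshold(5.0))
        assert len(evs) == 1
        assert evs[0].start_s < 10.5 and evs[0].stop_s > 13.5

    def test_short_bursts_dropped_long_kept(self):
        rec = self._burst_trace([(5.0, 5.5), (15.0, 17.0)])
        evs = nd.detect_active_periods(rec, self._threshold(5.0))
        assert len(evs) == 1
        assert abs(evs[0].start_s - 15.0) < 0.5

    def test_amplitude_scale_equivariance(self, neonatal_session):
        _, rec, _ = neonatal_session
        thr = nd.fit_detection_threshold(rec)
        e1 = nd.detect_active_periods(rec, thr)
        e2 = nd.detect_active_periods(rec.with_data(rec.data * 3.0), thr.rescaled(3.0))
        assert [(e.start_s, e.stop_s) for e in e1] == [(e.start_s, e.stop_s) for e in e2]
        assert np.allclose(
            [e.amplitude_uv * 3.0 for e in e1], [e.amplitude_uv for e in e2], rtol=1e-9
        )

    def test_recovers_ground_truth_bursts(self, neonatal_session):
        _, rec, truth = neonatal_session
        thr = nd.fit_detection_threshold(rec)
        evs = nd.detect_active_periods(rec, thr)
        strong = np.array(
            [[e.start_s, e.stop_s] for e in truth.events if e.snr >= 3.0]
        )
        recall, jaccard = nd.event_recall_jaccard(evs, strong)
        assert recall >= 0.9
        assert jaccard >= 0.8


class TestOccurrenceTimecourse:
    def test_full_minute_event_gives_one(self):
        evs = [nd.OscillationEvent(60.0, 120.0)]
        occ = nd.occurrence_timecourse(evs, total_s=180.0)
        assert np.allclose(occ, [0.0, 1.0, 0.0])

    def test_event_straddling_bins_splits_proportionally(self):
        evs = [nd.OscillationEvent(50.0, 80.0)]
        occ = nd.occurrence_timecourse(evs, total_s=120.0)
        assert occ[0] == pytest.approx(10.0 / 60.0)
        assert occ[1] == pytest.approx(20.0 / 60.0)

    def test_occurrence_plus_silence_is_one(self, neonatal_session):
        _, rec, truth = neonatal_session
        evs = [nd.OscillationEvent(e.start_s, e.stop_s) for e in truth.events]
        occ = nd.occurrence_timecourse(evs, total_s=rec.duration_s)
        silent = 1.0 - occ
        assert np.all((occ >= 0) & (occ <= 1))
        assert np.allclose(occ + silent, 1.0)

    def test_event_outside_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            nd.occurrence_timecourse([nd.OscillationEvent(100.0, 130.0)], total_s=120.0)
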