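"""Synthetic session generators: dose laws, spectra, spikes, artifacts."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import i0, i1

import neodepth as nd
from neodepth.preprocess import InvalidParameterError
from neodepth.metrics import band_power, modulation_index, welch_psd, windows_from_intervals


class TestColoredNoise:
    def test_reproducible_and_scaled(self, rng):
        a = nd.colored_noise(4096, 1000.0, -2.0, 3.0, np.random.default_rng(9))
        b = nd.colored_noise(4096, 1000.0, -2.0, 3.0, np.random.default_rng(9))
        assert np.array_equal(a, b)
        assert np.isclose(a.std(), 3.0)

    def test_spectral_slope_matches_exponent(self, rng):
        x = nd.colored_noise(120000, 1000.0, -2.0, 1.0, rng)
        psd = welch_psd(windows_from_intervals(x, 1000.0), 1000.0)
        est = nd.aperiodic_slope(psd, fit_range=(10.0, 100.0))
        assert abs(est.slope - (-2.0)) < 0.1

    def test_band_noise_confined_to_band(self, rng):
        x = nd.band_noise(60000, 1000.0, 10.0, 20.0, rng)
        psd = welch_psd(windows_from_intervals(x, 1000.0), 1000.0)
        inside = band_power(psd, (10.0, 20.0))
        outside = band_power(psd, (30.0, 100.0))
        assert inside > 100 * outside


class TestNeonatalSession:
    def test_bit_identical_under_same_seed(self):
        p = nd.NeonatalLfpParams(duration_s=60.0, seed=3)
        r1, t1 = nd.gen_neonatal_session(p)
        r2, t2 = nd.gen_neonatal_session(p)
        assert np.array_equal(r1.data, r2.data)
        assert [e.start_s for e in t1.events] == [e.start_s for e in t2.events]
        assert np.array_equal(t1.spike_times["PFC1"], t2.spike_times["PFC1"])

    def test_identity_dose_law_count_within_poisson_error(self):
        p = nd.NeonatalLfpParams(duration_s=600.0, seed=21)
        _, truth = nd.gen_neonatal_session(p)
        expected = p.burst_rate_hz * p.duration_s
        assert abs(len(truth.events) - expected) < 3 * math.sqrt(expected)

    def test_occupancy_conservation(self):
        p = nd.NeonatalLfpParams(duration_s=600.0, seed=22)
        _, truth = nd.gen_neonatal_session(p)
        covered = sum(e.duration_s for e in truth.events) / p.duration_s
        # configured occupancy = rate x mean truncated-normal duration
        assert abs(covered - 0.499) < 0.1

    def test_dose_ladder_occurrence_strictly_decreasing(self):
        dose = {0.0: 1.0, 1.0: 0.6, 2.0: 0.3, 3.0: 0.1}
        p = nd.NeonatalLfpParams(duration_s=2400.0, seed=5, dose_response=dose)
        ladder = [(0.0, 0.0), (600.0, 1.0), (1200.0, 2.0), (1800.0, 3.0)]
        _, truth = nd.gen_neonatal_session(p, ladder)
        occ = []
        for k in range(4):
            lo, hi = 600.0 * k, 600.0 * (k + 1)
            covered = sum(
                max(0.0, min(e.stop_s, hi) - max(e.start_s, lo)) for e in truth.events
            )
            occ.append(covered / 600.0)
        assert occ[0] > occ[1] > occ[2] > occ[3]

    def test_within_burst_spectrum_invariant_across_levels(self):
        dose = {0.0: 1.0, 2.0: 0.3}
        p = nd.NeonatalLfpParams(duration_s=1200.0, seed=8, dose_response=dose)
        rec, truth = nd.gen_neonatal_session(p, [(0.0, 0.0), (600.0, 2.0)])
        x = rec.data[0]
        fracs = []
        for level in (0.0, 2.0):
            iv = np.array([[e.start_s, e.stop_s] for e in truth.events if e.level == level])
            psd = welch_psd(windows_from_intervals(x, 1000.0, iv), 1000.0)
            bp = {n: band_power(psd, b) for n, b in nd.DEFAULT_BANDS.items()}
            tot = sum(bp.values())
            fracs.append({n: v / tot for n, v in bp.items()})
        for name in nd.DEFAULT_BANDS:
            assert abs(fracs[0][name] - fracs[1][name]) < 0.1

    def test_spike_phases_follow_von_mises_law(self):
        p = nd.NeonatalLfpParams(duration_s=600.0, seed=13, spike_lock_kappa=2.0)
        rec, truth = nd.gen_neonatal_session(p)
        phases = []
        from neodepth.preprocess import filter_array
        from scipy.signal import hilbert

        filt = filter_array(rec.data[0], *p.spike_lock_band, rec.sampling_rate_hz)
        phase = np.angle(hilbert(filt))
        idx = np.round(truth.spike_times["PFC1"] * rec.sampling_rate_hz).astype(int)
        phases = phase[idx]
        resultant = abs(np.mean(np.exp(1j * phases)))
        expected = i1(2.0) / i0(2.0)
        # Monte-Carlo error plus phase distortion from band overlap
        assert abs(resultant - expected) < 0.12

    def test_spikes_confined_to_bursts(self, neonatal_session):
        _, rec, truth = neonatal_session
        iv = truth.event_intervals()
        for t in truth.spike_times["PFC1"]:
            assert any(a - 1e-9 <= t <= b + 1e-9 for a, b in iv)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            nd.NeonatalLfpParams(duration_s=-5.0)
        with pytest.raises(InvalidParameterError):
            nd.NeonatalLfpParams(dose_response={0.0: 1.0, 1.0: 1.2})
        with pytest.raises(InvalidParameterError):
            nd.NeonatalLfpParams(dose_response={0.0: 0.5})
        with pytest.raises(InvalidParameterError):
            nd.NeonatalLfpParams(dose_response={0.0: 1.0, 1.0: 0.5, 2.0: 0.7})
        with pytest.raises(InvalidParameterError):
            p = nd.NeonatalLfpParams(duration_s=100.0)
            nd.gen_neonatal_session(p, [(0.0, 0.0), (200.0, 1.0)])


class TestJuvenileSession:
    fs = 1000.0

    def _session(self, slopes, seed=4):
        p = nd.NeonatalLfpParams(duration_s=240.0, seed=seed, band_dose_slopes=slopes)
        return nd.gen_juvenile_session(p, [(0.0, 0.0), (120.0, 1.0)])

    def _pre_post_psd(self, rec):
        x = rec.data[0]
        half = len(x) // 2
        pre = welch_psd(windows_from_intervals(x[:half], self.fs), self.fs)
        post = welch_psd(windows_from_intervals(x[half:], self.fs), self.fs)
        return pre, post

    def test_zero_slopes_leave_spectrum_unchanged(self):
        rec, _ = self._session({})
        pre, post = self._pre_post_psd(rec)
        for b in nd.DEFAULT_BANDS.values():
            mi = modulation_index(band_power(pre, b), band_power(post, b))
            assert abs(mi) < 0.1

    def test_slope_signs_set_modulation_directions(self):
        rec, _ = self._session({"delta": 0.8, "gamma": -0.8})
        pre, post = self._pre_post_psd(rec)
        assert modulation_index(
            band_power(pre, nd.DEFAULT_BANDS["delta"]), band_power(post, nd.DEFAULT_BANDS["delta"])
        ) > 0
        assert modulation_index(
            band_power(pre, nd.DEFAULT_BANDS["gamma"]), band_power(post, nd.DEFAULT_BANDS["gamma"])
        ) < 0

    def test_doubling_delta_slope_doubles_log_power_offset(self):
        offsets = []
        for slope in (0.5, 1.0):
            rec, _ = self._session({"delta": slope}, seed=6)
            pre, post = self._pre_post_psd(rec)
            offsets.append(
                math.log(
                    band_power(post, nd.DEFAULT_BANDS["delta"])
                    / band_power(pre, nd.DEFAULT_BANDS["delta"])
                )
            )
        assert abs(offsets[1] - 2 * offsets[0]) < 0.25 * abs(offsets[1])


class TestInfantSession:
    def test_negative_slope_gives_negative_amplitude_correlation(self, infant_session):
        _, rec, truth = infant_session
        env = nd.amplitude_envelope(rec).data.mean(axis=0)
        fs = rec.sampling_rate_hz
        med = [
            np.median(env[int(m * 60 * fs): int((m + 1) * 60 * fs)])
            for m in range(len(truth.concentration_per_minute))
        ]
        rho = nd.spearman_rho(med, truth.concentration_per_minute)
        assert rho < 0

    def test_zero_slope_correlation_within_null_band(self):
        p = nd.InfantEegParams(
            age_group="2-4",
            amplitude_dose_slope=0.0,
            n_channels=4,
            sampling_rate_hz=128.0,
            duration_min=24,
            seed=3,
        )
        rec, truth = nd.gen_infant_session(p)
        env = nd.amplitude_envelope(rec).data.mean(axis=0)
        fs = rec.sampling_rate_hz
        med = [
            np.median(env[int(m * 60 * fs): int((m + 1) * 60 * fs)])
            for m in range(24)
        ]
        assert abs(nd.spearman_rho(med, truth.concentration_per_minute)) < 0.5

    def test_artifact_mask_counts_injected_epochs(self):
        spec = nd.ArtifactSpec(n_saturation_epochs=3)
        p = nd.default_infant_params(
            "0-2", seed=2, n_channels=4, sampling_rate_hz=128.0,
            duration_min=25, artifact_spec=spec,
        )
        _, truth = nd.gen_infant_session(p)
        assert truth.artifact_mask.sum() == 3

    def test_too_few_channels_rejected(self):
        with pytest.raises(InvalidParameterError):
            nd.InfantEegParams(n_channels=1)

    def test_age_group_constrains_slope_sign(self):
        with pytest.raises(InvalidParameterError):
            nd.InfantEegParams(age_group="0-2", amplitude_dose_slope=0.3)
        with pytest.raises(InvalidParameterError):
            nd.InfantEegParams(age_group="4-6", amplitude_dose_slope=-0.3)

    def test_reproducible(self):
        p = nd.default_infant_params("4-6", seed=11, n_channels=3,
                                     sampling_rate_hz=128.0, duration_min=21)
        r1, _ = nd.gen_infant_session(p)
        r2, _ = nd.gen_infant_session(p)
        assert np.array_equal(r1.data, r2.data)


class TestGroundTruthIO:
    def test_json_round_trip(self, tmp_path, neonatal_session):
        _, _, truth = neonatal_session
        path = tmp_path / "truth.json"
        nd.write_ground_truth(truth, path)
        back = nd.read_ground_truth(path)
        assert len(back.events) == len(truth.events)
        assert back.events[0].start_s == truth.events[0].start_s
        assert np.array_equal(back.artifact_mask, truth.artifact_mask)
        assert np.allclose(back.spike_times["PFC1"], truth.spike_times["PFC1"])
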