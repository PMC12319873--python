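"""SSVEP pipeline: filtering, Laplacian, spectra, indices, phase."""

import numpy as np
import pandas as pd
import pytest

from dichopt.containers import MONTAGE_15, EEGRecording
from dichopt.ssvep import (
    amplitude_spectrum,
    average_trials,
    bandpass,
    check_exact_bins,
    condition_phase,
    condition_spectrum,
    im_amplitude,
    indices_from_amplitudes,
    laplacian_reference,
    lsq_phase,
    phase_to_delay,
    tagged_amplitude,
    wrap_phase,
)
from dichopt.synth.design import enumerate_conditions
from dichopt.synth.eegsim import SSVEPTruth, simulate_ssvep_recording


def _rec_from_array(data, srate=1000.0, trial_len_s=6.0, labels=None):
    n_trials = data.shape[1] // int(trial_len_s * srate)
    trials = pd.DataFrame(
        {
            "condition": ["c"] * n_trials,
            "onset_sample": np.arange(n_trials) * int(trial_len_s * srate),
        }
    )
    return EEGRecording(
        data=data,
        srate=srate,
        channel_labels=labels or list(MONTAGE_15[: data.shape[0]]),
        trials=trials,
        trial_len_s=trial_len_s,
    )


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(12000) / 1000.0
        rec = _rec_from_array(np.sin(2 * np.pi * 8 * t)[None, :], labels=["O1"])
        out = bandpass(rec, 1.0, 30.0).data[0]
        mid = slice(2000, 10000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_slow_drift_attenuated_40db(self):
        t = np.arange(30000) / 1000.0
        rec = _rec_from_array(np.sin(2 * np.pi * 0.2 * t)[None, :], labels=["O1"])
        out = bandpass(rec, 1.0, 30.0).data[0][10000:20000]
        assert np.abs(out).max() < 10 ** (-40 / 20)

    def test_zero_phase_burst_unshifted(self):
        t = np.arange(12000) / 1000.0
        env = np.exp(-0.5 * ((t - 6.0) / 0.5) ** 2)
        sig = env * np.sin(2 * np.pi * 10 * t)
        rec = _rec_from_array(sig[None, :], labels=["O1"])
        out = bandpass(rec, 1.0, 30.0).data[0]
        # zero-phase: the cross-correlation of output and input peaks at lag 0
        xc = np.correlate(out, sig, mode="full")
        lag = int(np.argmax(xc)) - (len(sig) - 1)
        assert abs(lag) <= 1

    def test_invalid_band_rejected(self):
        rec = _rec_from_array(np.zeros((1, 6000)), labels=["O1"])
        for lo, hi in [(30.0, 1.0), (0.0, 30.0), (1.0, 600.0)]:
            with pytest.raises(ValueError):
                bandpass(rec, lo, hi)


class TestLaplacian:
    def test_constant_channels(self):
        data = np.zeros((15, 100))
        data[:6] = 3.0  # central
        data[6:] = 1.0  # surround
        assert np.allclose(laplacian_reference(data, list(MONTAGE_15)), 2.0)

    def test_common_mode_rejected(self):
        rng = np.random.default_rng(0)
        common = rng.standard_normal(500)
        data = np.tile(common, (15, 1))
        assert np.abs(laplacian_reference(data, list(MONTAGE_15))).max() < 1e-12

    def test_central_component_passes_with_unit_gain(self):
        t = np.arange(5000) / 1000.0
        data = np.zeros((15, 5000))
        data[:6] = 0.7 * np.sin(2 * np.pi * 8 * t)
        out = laplacian_reference(data, list(MONTAGE_15))
        assert np.abs(out).max() == pytest.approx(0.7, rel=0.01)

    def test_missing_channel_named(self):
        data = np.zeros((14, 10))
        labels = [ch for ch in MONTAGE_15 if ch != "POz"]
        with pytest.raises(KeyError, match="POz"):
            laplacian_reference(data, labels)


class TestAverageTrials:
    def test_single_trial_identity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 6000))
        rec = _rec_from_array(data, labels=["O1", "O2"])
        out = average_trials(rec, "c", window=(1.0, 6.0))
        assert np.array_equal(out, data[:, 1000:6000])

    def test_window_length_is_5s(self):
        rec = _rec_from_array(np.zeros((1, 18000)), labels=["O1"])
        out = average_trials(rec, "c", window=(1.0, 6.0))
        assert out.shape[1] == 5000

    def test_snr_gain_sqrt_n(self):
        rng = np.random.default_rng(2)
        n_trials = 20
        t = np.arange(6000) / 1000.0
        sig = np.sin(2 * np.pi * 8 * t)
        data = np.tile(sig, n_trials)[None, :] + rng.standard_normal((1, 6000 * n_trials))
        rec = _rec_from_array(data, labels=["O1"])
        out = average_trials(rec, "c", window=(1.0, 6.0))[0]
        resid = out - sig[1000:6000]
        gain = 1.0 / resid.std()
        assert gain == pytest.approx(np.sqrt(n_trials), rel=0.2)

    def test_missing_condition_rejected(self):
        rec = _rec_from_array(np.zeros((1, 6000)), labels=["O1"])
        with pytest.raises(ValueError):
            average_trials(rec, "nope")


class TestSpectrum:
    def test_unit_sinusoid_normalization(self):
        t = np.arange(5000) / 1000.0
        spec = amplitude_spectrum(np.sin(2 * np.pi * 8 * t), 1000.0)
        assert spec.resolution == pytest.approx(0.2)
        assert spec.at(8.0) == pytest.approx(1.0, abs=1e-9)

    def test_two_tones_resolved_no_leakage(self):
        t = np.arange(5000) / 1000.0
        sig = 1.0 * np.sin(2 * np.pi * 7.2 * t) + 0.5 * np.sin(2 * np.pi * 8 * t)
        spec = amplitude_spectrum(sig, 1000.0)
        assert spec.at(7.2) == pytest.approx(1.0, abs=1e-9)
        assert spec.at(8.0) == pytest.approx(0.5, abs=1e-9)
        others = np.delete(spec.amp, [spec._bin(7.2), spec._bin(8.0)])
        assert others.max() < 1e-9

    def test_parseval(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal(5000)
        spec = amplitude_spectrum(sig, 1000.0)
        # energy of the single-sided amplitude spectrum (DC and Nyquist
        # bins are not doubled in the single-sided convention)
        energy = (
            spec.amp[0] ** 2
            + spec.amp[-1] ** 2
            + 0.5 * np.sum(spec.amp[1:-1] ** 2)
        ) * len(sig)
        assert energy == pytest.approx(np.sum(sig**2), rel=1e-6)

    def test_off_grid_frequency_rejected_with_offset(self):
        t = np.arange(5000) / 1000.0
        spec = amplitude_spectrum(np.sin(2 * np.pi * 8 * t), 1000.0)
        with pytest.raises(ValueError, match="offset"):
            spec.at(8.05)

    def test_tagged_amplitude_sums_harmonics(self):
        t = np.arange(5000) / 1000.0
        sig = 2.0 * np.cos(2 * np.pi * 7.2 * t) + 1.0 * np.cos(2 * np.pi * 14.4 * t)
        spec = amplitude_spectrum(sig, 1000.0)
        assert tagged_amplitude(spec, 7.2).amp_sum == pytest.approx(3.0, abs=1e-9)

    def test_im_bin_distinct_from_harmonics(self):
        spec = amplitude_spectrum(np.zeros(5000), 1000.0)
        bins = {spec._bin(f) for f in (14.4, 16.0, 15.2)}
        assert len(bins) == 3

    def test_exact_bin_contract(self):
        check_exact_bins()  # must not raise for the standard windows
        with pytest.raises(ValueError):
            check_exact_bins(window_s=4.7)


class TestIndices:
    def test_arithmetic(self):
        out = indices_from_amplitudes(2.0, 4.0, 1.0, 3.8)
        assert out["ADI_mono"] == pytest.approx(0.5)
        assert out["ADI_bino"] == pytest.approx((3.8 - 1.0) / 3.8)
        assert out["BSI_AE"] == pytest.approx(0.5)
        assert out["BSI_FE"] == pytest.approx(0.05)

    def test_no_suppression(self):
        out = indices_from_amplitudes(2.0, 3.0, 2.0, 3.0)
        assert out["BSI_AE"] == out["BSI_FE"] == 0.0

    def test_noise_floor_flag(self):
        out = indices_from_amplitudes(0.2, 3.0, 0.1, 2.9, noise_floor=0.25)
        assert out["unreliable"]
        with pytest.raises(ValueError):
            indices_from_amplitudes(0.0, 3.0, 0.1, 2.9)

    def test_amplitude_scaling_leaves_indices_unchanged(self):
        base = indices_from_amplitudes(2.0, 4.0, 1.0, 3.8)
        scaled = indices_from_amplitudes(6.0, 12.0, 3.0, 11.4)
        for k in ("ADI_mono", "ADI_bino", "BSI_AE", "BSI_FE"):
            assert scaled[k] == pytest.approx(base[k])


class TestPhase:
    srate = 1000.0

    def test_cosine_convention(self):
        t = np.arange(3750) / self.srate
        assert lsq_phase(np.cos(2 * np.pi * 8 * t), 8.0, self.srate).phase == pytest.approx(0.0, abs=1e-9)
        assert lsq_phase(np.sin(2 * np.pi * 8 * t), 8.0, self.srate).phase == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_planted_delay_recovered(self):
        t = np.arange(3750) / self.srate
        delayed = np.cos(2 * np.pi * 7.2 * (t - 0.01281))
        ref = np.cos(2 * np.pi * 7.2 * t)
        pa = lsq_phase(ref, 7.2, self.srate).phase
        pb = lsq_phase(delayed, 7.2, self.srate).phase
        assert phase_to_delay(pa, pb, 7.2) == pytest.approx(12.81, abs=0.1)

    def test_noninteger_cycles_warn(self):
        t = np.arange(3700) / self.srate
        with pytest.warns(UserWarning, match="cycles"):
            lsq_phase(np.cos(2 * np.pi * 7.2 * t), 7.2, self.srate)

    def test_delay_arithmetic_and_wrap(self):
        assert phase_to_delay(np.pi / 4, 0.0, 8.0) == pytest.approx(15.625)
        assert phase_to_delay(0.3, 0.3, 8.0) == 0.0
        # wrap: almost-full-cycle difference is a small negative delay
        eps = 1e-3
        d = phase_to_delay(2 * np.pi - eps, 0.0, 8.0)
        assert -1.0 < d < 0.0
        with pytest.raises(ValueError):
            phase_to_delay(0.1, 0.2, -8.0)

    def test_wrap_phase_range(self):
        x = wrap_phase(np.linspace(-10, 10, 1001))
        assert (x > -np.pi).all() and (x <= np.pi).all()
        assert wrap_phase(np.pi) == pytest.approx(np.pi)


class TestSimulatedRecordings:
    def _truth(self, **kw):
        base = dict(
            amp1={"AE": 1.3, "FE": 2.0},
            amp2={"AE": 0.5, "FE": 0.8},
            im_amp=0.3,
            latency_ms={"AE": 12.81, "FE": 0.0},
            bsi={"AE": 0.4, "FE": 0.05},
            noise_sd=0.0,
        )
        base.update(kw)
        return SSVEPTruth(**base)

    @pytest.fixture()
    def low_conditions(self):
        return [c for c in enumerate_conditions() if c[0] == "low"]

    def test_determinism(self, low_conditions):
        truth = self._truth(noise_sd=1.0)
        a = simulate_ssvep_recording(truth, 2, seed=3, conditions=low_conditions)
        b = simulate_ssvep_recording(truth, 2, seed=3, conditions=low_conditions)
        c = simulate_ssvep_recording(truth, 2, seed=4, conditions=low_conditions)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_monocular_condition_contains_only_that_eyes_tags(self, low_conditions):
        rec = simulate_ssvep_recording(self._truth(), 1, seed=0, conditions=low_conditions)
        spec = condition_spectrum(rec, "low/AE/f1=AE")
        # the long filter kernel bleeds a little of the neighboring trials
        # into the window, so "absent" means orders of magnitude down
        assert spec.at(7.2) > 0.5  # AE tagged at 7.2
        assert spec.at(8.0) < 0.01 * spec.at(7.2)  # FE tag absent
        assert spec.at(15.2) < 0.01 * spec.at(7.2)  # no IM without both eyes

    def test_zero_bsi_binocular_equals_monocular(self, low_conditions):
        truth = self._truth(bsi={"AE": 0.0, "FE": 0.0})
        rec = simulate_ssvep_recording(truth, 1, seed=0, conditions=low_conditions)
        mono = condition_spectrum(rec, "low/AE/f1=AE").at(7.2)
        bino = condition_spectrum(rec, "low/binocular/f1=AE").at(7.2)
        assert bino == pytest.approx(mono, rel=2e-3)  # filter edge effects only

    def test_zero_im_at_noise_floor(self, low_conditions):
        truth = self._truth(im_amp=0.0, noise_sd=0.5)
        rec = simulate_ssvep_recording(truth, 4, seed=1, conditions=low_conditions)
        spec = condition_spectrum(rec, "low/binocular/f1=AE")
        floor = spec.noise_floor(15.2)
        assert im_amplitude(spec, 7.2, 8.0) < 5 * floor

    def test_planted_im_recovered(self, low_conditions):
        rec = simulate_ssvep_recording(self._truth(), 1, seed=0, conditions=low_conditions)
        spec = condition_spectrum(rec, "low/binocular/f1=AE")
        # Laplacian gain: central 1.0 minus surround 0.2
        assert im_amplitude(spec, 7.2, 8.0) == pytest.approx(0.3 * 0.8, rel=0.02)

    def test_amplitude_linearity(self, low_conditions):
        t1 = self._truth()
        t2 = self._truth(
            amp1={"AE": 2.6, "FE": 4.0}, amp2={"AE": 1.0, "FE": 1.6}, im_amp=0.6
        )
        r1 = simulate_ssvep_recording(t1, 1, seed=0, conditions=low_conditions)
        r2 = simulate_ssvep_recording(t2, 1, seed=0, conditions=low_conditions)
        s1 = condition_spectrum(r1, "low/binocular/f1=AE")
        s2 = condition_spectrum(r2, "low/binocular/f1=AE")
        for f in (7.2, 8.0, 14.4, 16.0, 15.2):
            assert s2.at(f) == pytest.approx(2 * s1.at(f), rel=1e-4, abs=1e-9)

    def test_phase_recovery_with_noise_within_1ms(self, low_conditions):
        """Planted 12.81 ms AE delay recovered within 1 ms at SNR >= 10."""
        truth = self._truth(noise_sd=1.0)  # amplitude ~1.3-2.0 uV, 20 trials
        rec = simulate_ssvep_recording(truth, 20, seed=5, conditions=low_conditions)
        pa = condition_phase(rec, "low/FE/f1=FE", 7.2)
        pb = condition_phase(rec, "low/AE/f1=AE", 7.2)
        delay = phase_to_delay(pa.phase, pb.phase, 7.2)
        assert delay == pytest.approx(12.81, abs=1.0)

    def test_short_trials_rejected(self):
        with pytest.raises(ValueError):
            simulate_ssvep_recording(self._truth(), 1, trial_s=4.0)

    def test_off_grid_tag_warns(self, low_conditions):
        truth = self._truth()
        with pytest.warns(UserWarning, match="off the"):
            simulate_ssvep_recording(
                truth, 1, seed=0, conditions=low_conditions, analysis_window_s=4.7
            )
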