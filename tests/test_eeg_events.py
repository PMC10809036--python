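import numpy as np
import pytest

from szdetect.eeg_events import (
    EEGRecording,
    EEGSpikeSet,
    SWDKernel,
    build_swd_kernel,
    detect_eeg_spikes_threshold,
    recover_missed_spikes,
    robust_sd,
    spectral_ratio_filter,
)

FS = 2000.0


def _noise_eeg(duration, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(0, sd, int(duration * FS))


def _bump(width_s, amp):
    t = np.arange(-width_s, width_s, 1 / FS)
    return amp * np.exp(-(t**2) / (2 * (width_s / 4) ** 2))


def _insert(sig, wave, t):
    i = int(t * FS) - len(wave) // 2
    sig[i : i + len(wave)] += wave
    return sig


class TestThresholdDetection:
    def test_single_deflection_found(self):
        sig = _insert(_noise_eeg(20, seed=3), _bump(0.05, 10.0), 10.0)
        spikes = detect_eeg_spikes_threshold(EEGRecording(sig, FS))
        assert len(spikes) == 1
        assert spikes.times[0] == pytest.approx(10.0, abs=0.02)

    def test_pure_noise_high_threshold_empty(self):
        spikes = detect_eeg_spikes_threshold(EEGRecording(_noise_eeg(20, seed=4), FS), k_sd=10)
        assert len(spikes) == 0

    def test_min_separation_keeps_larger(self):
        sig = _noise_eeg(20, sd=0.5, seed=5)
        _insert(sig, _bump(0.05, 9.0), 10.0)
        _insert(sig, _bump(0.05, 10.0), 10.3)
        spikes = detect_eeg_spikes_threshold(EEGRecording(sig, FS), min_separation=0.7)
        assert len(spikes) == 1
        assert spikes.times[0] == pytest.approx(10.3, abs=0.02)

    def test_flat_signal_warns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            spikes = detect_eeg_spikes_threshold(EEGRecording(np.zeros(int(5 * FS)), FS))
        assert len(spikes) == 0

    def test_negative_deflection_found(self):
        sig = _insert(_noise_eeg(20, seed=6), _bump(0.05, -10.0), 8.0)
        spikes = detect_eeg_spikes_threshold(EEGRecording(sig, FS))
        assert np.min(np.abs(spikes.times - 8.0)) < 0.02


class TestSpectralRatioFilter:
    def _eeg_with_burst(self, freq, t_spike=5.0, span=(-0.5, 2.0), amp=1.0):
        sig = _noise_eeg(12, sd=0.02, seed=7)
        t = np.arange(len(sig)) / FS
        mask = (t >= t_spike + span[0]) & (t <= t_spike + span[1])
        sig[mask] += amp * np.sin(2 * np.pi * freq * t[mask])
        return EEGRecording(sig, FS)

    def test_theta_alpha_burst_kept(self):
        eeg = self._eeg_with_burst(10.0, span=(-0.3, 0.6))
        spikes = EEGSpikeSet(times=np.array([5.0]))
        kept = spectral_ratio_filter(eeg, spikes)
        assert len(kept) == 1

    def test_gamma_burst_removed(self):
        eeg = self._eeg_with_burst(40.0, span=(-0.5, 2.0))
        spikes = EEGSpikeSet(times=np.array([5.0]))
        kept = spectral_ratio_filter(eeg, spikes)
        assert len(kept) == 0

    def test_isi_rule_removes_second(self):
        # both spikes sit in a sustained 10 Hz oscillation so both pass the ratio
        eeg = self._eeg_with_burst(10.0, t_spike=5.0, span=(-0.5, 3.0))
        spikes = EEGSpikeSet(times=np.array([5.0, 5.5]))
        kept = spectral_ratio_filter(eeg, spikes)
        assert list(kept.times) == [5.0]

    def test_boundary_window_truncates_with_warning(self):
        eeg = self._eeg_with_burst(10.0, t_spike=11.6, span=(-0.5, 0.5))
        spikes = EEGSpikeSet(times=np.array([11.6]))
        with pytest.warns(UserWarning, match="truncated"):
            spectral_ratio_filter(eeg, spikes)

    def test_never_adds_spikes(self):
        eeg = self._eeg_with_burst(10.0)
        spikes = EEGSpikeSet(times=np.array([2.0, 5.0, 8.0]))
        kept = spectral_ratio_filter(eeg, spikes)
        assert set(kept.times) <= set(spikes.times)


class TestSWDKernel:
    def test_mean_of_identical_segments(self):
        sig = _noise_eeg(60, sd=0.0, seed=0)
        wave = _bump(0.05, 3.0)
        times = [10.0, 20.0, 30.0]
        for t in times:
            _insert(sig, wave, t)
        kernel = build_swd_kernel(EEGRecording(sig, FS), np.array(times), half_width=0.5)
        center = len(kernel.waveform) // 2
        assert kernel.waveform[center] == pytest.approx(3.0, rel=1e-6)
        assert len(kernel.waveform) == 2 * int(0.5 * FS) + 1

    def test_opposite_waveforms_cancel(self):
        sig = np.zeros(int(60 * FS))
        _insert(sig, _bump(0.05, 3.0), 10.0)
        _insert(sig, _bump(0.05, -3.0), 20.0)
        kernel = build_swd_kernel(EEGRecording(sig, FS), np.array([10.0, 20.0]))
        assert np.max(np.abs(kernel.waveform)) < 1e-9

    def test_noise_averages_down(self):
        rng = np.random.default_rng(11)
        sig = rng.normal(0, 1.0, int(300 * FS))
        wave = _bump(0.05, 5.0)
        times = np.arange(2.0, 252.0, 5.0)  # 50 segments
        for t in times:
            _insert(sig, wave, t)
        kernel = build_swd_kernel(EEGRecording(sig, FS), times)
        center = len(kernel.waveform) // 2
        # residual noise ~ 1/sqrt(50); allow 4 SE
        assert abs(kernel.waveform[center] - 5.0) < 4 / np.sqrt(50)

    def test_empty_times_raises(self):
        with pytest.raises(ValueError, match="concordant"):
            build_swd_kernel(EEGRecording(_noise_eeg(5), FS), np.array([]))

    def test_out_of_bounds_window_raises(self):
        with pytest.raises(ValueError, match="bounds"):
            build_swd_kernel(EEGRecording(_noise_eeg(5), FS), np.array([0.1]))


class TestKernelRecovery:
    def _kernel(self, amp=4.0):
        wave = np.zeros(2 * int(0.5 * FS) + 1)
        bump = _bump(0.05, amp)
        c = len(wave) // 2 - len(bump) // 2
        wave[c : c + len(bump)] += bump
        return SWDKernel(waveform=wave, half_width=0.5, fs=FS)

    def test_inserted_kernel_recovered_at_location(self):
        sig = _noise_eeg(120, sd=0.3, seed=8)
        _insert(sig, _bump(0.05, 4.0), 100.0)
        eeg = EEGRecording(sig, FS)
        out = recover_missed_spikes(eeg, self._kernel(), EEGSpikeSet(times=np.array([])))
        assert len(out) >= 1
        assert np.min(np.abs(out.times - 100.0)) < 0.05

    def test_existing_spike_not_duplicated(self):
        sig = _noise_eeg(120, sd=0.3, seed=9)
        _insert(sig, _bump(0.05, 4.0), 60.0)
        eeg = EEGRecording(sig, FS)
        existing = EEGSpikeSet(times=np.array([60.0]))
        out = recover_missed_spikes(eeg, self._kernel(), existing)
        assert len(out) == 1

    def test_subthreshold_not_recovered(self):
        sig = _noise_eeg(120, sd=1.0, seed=10)
        _insert(sig, _bump(0.05, 0.5), 100.0)
        eeg = EEGRecording(sig, FS)
        out = recover_missed_spikes(eeg, self._kernel(), EEGSpikeSet(times=np.array([])))
        assert not np.any(np.abs(out.times - 100.0) < 0.1)

    def test_never_removes_spikes(self):
        sig = _noise_eeg(60, sd=0.3, seed=12)
        eeg = EEGRecording(sig, FS)
        existing = EEGSpikeSet(times=np.array([5.0, 15.0, 25.0]))
        out = recover_missed_spikes(eeg, self._kernel(), existing)
        assert set(existing.times) <= set(out.times)


class TestInvariantsAndTypes:
    def test_robust_sd_gaussian(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 200000)
        assert robust_sd(x) == pytest.approx(2.0, rel=0.02)

    def test_spike_set_sorted_and_validated(self):
        s = EEGSpikeSet(times=np.array([3.0, 1.0, 2.0]))
        assert list(s.times) == [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="increasing"):
            EEGSpikeSet(times=np.array([1.0, 1.0]))

    def test_kernel_length_validated(self):
        with pytest.raises(ValueError, match="length"):
            SWDKernel(waveform=np.zeros(100), half_width=0.5, fs=FS)

    def test_eeg_recording_validation(self):
        with pytest.raises(ValueError, match="sampling rate"):
            EEGRecording(samples=np.zeros(100), fs=500.0)
        with pytest.raises(ValueError, match="finite"):
            EEGRecording(samples=np.array([1.0, np.nan]), fs=FS)
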