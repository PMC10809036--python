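"""EEG spike-wave-discharge (SWD) detection.

Three stages: amplitude-threshold candidate detection, spectral-power-ratio
exclusion, and matched-kernel recovery of low-amplitude spikes missed by the
threshold stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EEGSpikeSet",
    "SWDKernel",
    "robust_sd",
    "detect_eeg_spikes_threshold",
    "spectral_ratio_filter",
    "build_swd_kernel",
    "recover_missed_spikes",
]

SOURCE_THRESHOLD = "threshold"
SOURCE_KERNEL = "kernel_recovered"


@dataclass
class EEGRecording:
    """Single-channel EEG, time-locked to the imaging trigger (t0 = 0)."""

    samples: np.ndarray
    fs: float
    bandpass: tuple[float, float] = (0.5, 300.0)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 2 * self.bandpass[1]:
            raise ValueError("sampling rate must exceed twice the upper bandpass edge")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class EEGSpikeSet:
    """Sorted SWD peak times with per-spike provenance tags."""

    times: np.ndarray
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if not self.sources:
            self.sources = [SOURCE_THRESHOLD] * len(self.times)
        if len(self.sources) != len(self.times):
            raise ValueError("sources length must match times length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.sources = [self.sources[i] for i in order]
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SWDKernel:
    """Mean SWD waveform, centered on the spike peak."""

    waveform: np.ndarray
    half_width: float
    fs: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        expected = 2 * int(round(self.half_width * self.fs)) + 1
        if len(self.waveform) != expected:
            raise ValueError(
                f"kernel length {len(self.waveform)} != 2*half_width*fs + 1 = {expected}"
            )


def robust_sd(x: np.ndarray) -> float:
    """Robust standard deviation: MAD about the median, scaled by 1.4826."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_eeg_spikes_threshold(
    eeg: EEGRecording, k_sd: float = 4.5, min_separation: float = 0.7
) -> EEGSpikeSet:
    """Amplitude-threshold candidate detection.

    Peaks where ``|signal - median|`` exceeds ``k_sd`` robust standard
    deviations, indexed at the local absolute-value maximum and separated by
    at least ``min_separation`` seconds (the larger peak wins).
    """
    if eeg.n_samples == 0:
        raise ValueError("EEG recording is empty")
    sd = robust_sd(eeg.samples)
    if sd == 0:
        warnings.warn("flat EEG signal (robust SD = 0); no spikes detected")
        return EEGSpikeSet(times=np.empty(0), sources=[])
    a = np.abs(eeg.samples - np.median(eeg.samples))
    distance = max(1, int(round(min_separation * eeg.fs)))
    peaks, _ = sps.find_peaks(a, height=k_sd * sd, distance=distance)
    times = eeg.t0 + peaks / eeg.fs
    return EEGSpikeSet(times=times, sources=[SOURCE_THRESHOLD] * len(times))


def _welch_band_power(x: np.ndarray, fs: float, lo: float, hi: float, nperseg_s: float) -> float:
    nperseg = min(len(x), max(8, int(round(nperseg_s * fs))))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return float(p[mask].sum())
    return float(np.trapezoid(p[mask], f[mask]))


def spectral_ratio_filter(
    eeg: EEGRecording,
    spikes: EEGSpikeSet,
    ratio_min: float = 20.0,
    isi_min: float = 0.7,
    window: float = 1.0,
    pre: float = 0.25,
    nperseg_s: float = 0.5,
) -> EEGSpikeSet:
    """Exclude candidates lacking SWD-like spectral content.

    For each spike, the ratio of theta-alpha (3-15 Hz) Welch band power over
    a 1-s window starting ``pre`` seconds before the peak, to low-gamma
    (20-55 Hz) power over the immediately following 1-s window.  Spikes with
    ratio below ``ratio_min`` are removed, then spikes closer than
    ``isi_min`` to their predecessor are removed (earlier kept).
    """
    kept_times: list[float] = []
    kept_sources: list[str] = []
    n = eeg.n_samples
    for t, src in zip(spikes.times, spikes.sources):
        i0 = int(round((t - eeg.t0 - pre) * eeg.fs))
        i1 = i0 + int(round(window * eeg.fs))
        i2 = i1 + int(round(window * eeg.fs))
        if i0 < 0 or i2 > n:
            warnings.warn(f"spectral window for spike at {t:.3f}s truncated at record boundary")
            i0, i1, i2 = max(i0, 0), min(max(i1, 1), n), min(i2, n)
        seg_a = eeg.samples[i0:i1]
        seg_b = eeg.samples[i1:i2]
        if len(seg_a) < 8 or len(seg_b) < 8:
            continue
        p_low = _welch_band_power(seg_a, eeg.fs, 3.0, 15.0, nperseg_s)
        p_gamma = _welch_band_power(seg_b, eeg.fs, 20.0, 55.0, nperseg_s)
        ratio = np.inf if p_gamma == 0 else p_low / p_gamma
        if ratio >= ratio_min:
            kept_times.append(float(t))
            kept_sources.append(src)

    # inter-spike-interval rule: drop followers closer than isi_min
    final_t: list[float] = []
    final_s: list[str] = []
    for t, src in zip(kept_times, kept_sources):
        if final_t and t - final_t[-1] < isi_min:
            continue
        final_t.append(t)
        final_s.append(src)
    return EEGSpikeSet(times=np.asarray(final_t), sources=final_s)


def build_swd_kernel(
    eeg: EEGRecording, concordant_times: np.ndarray, half_width: float = 0.5
) -> SWDKernel:
    """Mean EEG waveform over ``[t - half_width, t + half_width]`` windows."""
    concordant_times = np.asarray(concordant_times, dtype=float).ravel()
    if len(concordant_times) == 0:
        raise ValueError("no concordant spikes: cannot build SWD kernel")
    hw = int(round(half_width * eeg.fs))
    segments = []
    for t in concordant_times:
        c = int(round((t - eeg.t0) * eeg.fs))
        if c - hw < 0 or c + hw + 1 > eeg.n_samples:
            raise ValueError(f"kernel window around {t:.3f}s extends past record bounds")
        segments.append(eeg.samples[c - hw : c + hw + 1])
    return SWDKernel(waveform=np.mean(segments, axis=0), half_width=half_width, fs=eeg.fs)


def recover_missed_spikes(
    eeg: EEGRecording,
    kernel: SWDKernel,
    existing: EEGSpikeSet,
    k_sd: float = 5.0,
    min_separation: float = 1.0,
    dedup_tol: float = 0.5,
) -> EEGSpikeSet:
    """Matched-kernel recovery of spikes missed by threshold detection.

    The EEG is cross-correlated with the kernel (lag-corrected so maxima
    align with the kernel center); local maxima at least ``k_sd`` standard
    deviations above the correlation-trace mean and ``min_separation`` apart
    are candidate spikes.  Candidates within ``dedup_tol`` of an existing
    spike are dropped; the rest are appended with a ``kernel_recovered`` tag.
    """
    # 'same'-mode correlation: for the odd-length, peak-centered kernel this
    # places the correlation maximum at the sample where the waveform peaks.
    corr = sps.oaconvolve(eeg.samples, kernel.waveform[::-1], mode="same")
    mu, sd = float(np.mean(corr)), float(np.std(corr))
    if sd == 0:
        return existing
    distance = max(1, int(round(min_separation * eeg.fs)))
    peaks, _ = sps.find_peaks(corr, height=mu + k_sd * sd, distance=distance)
    new_times = eeg.t0 + peaks / eeg.fs

    times = list(existing.times)
    sources = list(existing.sources)
    for t in new_times:
        if len(existing.times) and np.min(np.abs(existing.times - t)) <= dedup_tol:
            continue
        times.append(float(t))
        sources.append(SOURCE_KERNEL)
    logger.info("kernel recovery appended %d spike(s)", len(times) - len(existing.times))
    return EEGSpikeSet(times=np.asarray(times), sources=sources)
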