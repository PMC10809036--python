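"""Synthetic paired calcium + EEG recordings with exported ground truth.

Generates recordings exhibiting the full seizure phenomenology: pre-ictal
spike trains visible in both modalities, a sentinel spike, a fast planar
ictal wavefront with a sustained plateau, a slow terminal spreading wave,
indicator-kinetics-shaped transients, photobleaching, and realistic noise.
Every planted event is returned as ground truth so each pipeline stage can
be validated without external data.

Ground-truth recruitment times are the points of steepest slope of the
noise-free low-pass-filtered traces (the definition of an event time used
throughout the package); the planted planar-wave delays are additionally
stored as ``*_geo`` times for propagation-model validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_events import EEGRecording, robust_sd
from .signal_core import CalciumRecording, preprocess_traces, zero_phase_lowpass

__all__ = ["SimConfig", "GroundTruth", "generate_recording", "export_fixture"]


@dataclass
class SimConfig:
    """Parameters of a synthetic recording.  All times in seconds."""

    n_cells: int = 50
    duration: float = 300.0
    frame_rate: float = 30.0
    eeg_fs: float = 2000.0
    field_size: float = 400.0  # micrometers

    # pre-ictal spikes
    pis_rate: float = 3.0  # events per minute
    pis_start: float = 40.0
    pis_min_gap: float = 4.0
    pis_stop_margin: float = 10.0  # PIS train ends this long before seizure onset
    pis_participation: float = 0.8
    pis_jitter: float = 0.1  # per-cell recruitment jitter SD
    pis_amp: float = 1.5  # dF/F0
    pis_amp_jitter: float = 0.0  # lognormal sigma of per-event amplitude

    # sentinel spike
    sentinel: bool = True
    sentinel_amp: float = 2.5
    sentinel_lead: tuple[float, float] = (2.5, 4.0)  # seconds before seizure onset

    # seizure wavefront
    seizure: bool = True
    seizure_onset: float = 200.0
    seizure_velocity: float = 421.0  # um/s
    seizure_angle: float = 0.0  # degrees, propagation direction
    seizure_amp: float = 3.0
    seizure_duration: float = 20.0
    seizure_rise_scale: float = 0.15  # logistic time scale of the wavefront rise
    seizure_participation: float = 1.0

    # terminal spreading wave
    terminal: bool = True
    terminal_onset: float = 255.0
    terminal_velocity: float = 68.0
    terminal_angle: float = 152.0
    terminal_amp: float = 2.5
    terminal_hold: float = 4.0
    terminal_rise_scale: float = 0.25
    terminal_participation: float = 1.0

    # indicator kinetics (half-decay ~1.4 s jYCaMP1s-like, ~0.4 s jRGECO1a-like)
    indicator_half_decay: float = 1.4
    rise_time: float = 0.1

    # ongoing physiological background transients
    background_rate: float = 0.5  # Hz per cell
    background_amp: float = 0.08

    # noise / nuisance
    noise_sd: float = 0.1  # white noise SD on somatic dF/F0
    noise_sd_range: tuple[float, float] | None = None  # per-cell log-uniform range
    neuropil_noise_frac: float = 0.3
    drift_amp: float = 0.0
    drift_period: float = 60.0
    bleach_end: float = 0.8  # multiplicative photobleach level at end of recording

    # raw-fluorescence reconstruction
    soma_f0: float = 100.0
    neuropil_f0: float = 80.0
    f0_spread: float = 0.15
    background_level: float = 10.0
    neuropil_coeff: float = 0.7

    # EEG
    eeg_noise: float = 1.0
    eeg_exponent: float = 2.0  # 1/f^exponent noise power
    swd_amp: float = 8.0  # x robust SD of the EEG noise
    sentinel_eeg_amp: float = 12.0
    ictal_eeg_amp: float = 5.0
    ictal_eeg_freq: float = 28.0

    filter_cutoff: float = 1.0  # used for ground-truth steepest-slope times
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("duration", "frame_rate", "eeg_fs", "field_size", "pis_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.pis_participation <= 1:
            raise ValueError("pis_participation must be in [0, 1]")
        if self.pis_start < 35.0:
            raise ValueError("pis_start must leave a clean 30-s baseline window")
        if self.terminal and not self.seizure:
            raise ValueError("terminal wave requires a seizure")
        if self.seizure:
            cross = np.sqrt(2) * self.field_size / self.seizure_velocity
            sz_end = self.seizure_onset + cross + self.seizure_duration
            if self.terminal:
                if sz_end + 5 > self.terminal_onset:
                    raise ValueError("seizure plateau must end before the terminal wave")
                t_end = (
                    self.terminal_onset
                    + np.sqrt(2) * self.field_size / self.terminal_velocity
                    + self.terminal_hold
                )
                if t_end + 10 > self.duration:
                    raise ValueError("terminal wave does not fit in the recording")
            elif sz_end + 5 > self.duration:
                raise ValueError("seizure does not fit in the recording")
            if self.seizure_onset - self.pis_stop_margin <= self.pis_start:
                raise ValueError("no room for a pre-ictal period")

    @property
    def tau_decay(self) -> float:
        return self.indicator_half_decay / np.log(2.0)


@dataclass
class GroundTruth:
    """Planted events of a synthetic recording.

    ``pis_times`` are the canonical population PIS times (EEG SWD peaks),
    including the sentinel spike when present.  ``cell_*_times`` hold the
    per-cell steepest-slope recruitment times (NaN for non-participating
    cells); ``cell_*_times_geo`` hold the planted planar-wave delays.
    """

    pis_times: np.ndarray
    participation: np.ndarray  # (n_cells, n_pis) bool
    cell_pis_times: np.ndarray  # (n_cells, n_pis), NaN if not participating
    sentinel_time: float | None = None
    seizure_seed_time: float | None = None
    terminal_seed_time: float | None = None
    cell_seizure_times: np.ndarray | None = None
    cell_terminal_times: np.ndarray | None = None
    cell_seizure_times_geo: np.ndarray | None = None
    cell_terminal_times_geo: np.ndarray | None = None
    wave_params: dict = field(default_factory=dict)
    noise_sd_per_cell: np.ndarray | None = None

    @property
    def eeg_swd_times(self) -> np.ndarray:
        return self.pis_times

    def pis_times_by_cell(self) -> dict[int, np.ndarray]:
        """Participating per-cell PIS recruitment times, keyed by cell."""
        return {
            i: self.cell_pis_times[i][np.isfinite(self.cell_pis_times[i])]
            for i in range(self.cell_pis_times.shape[0])
        }


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -60, 60)))


def _add_transient(
    trace: np.ndarray,
    frame_rate: float,
    onset: float,
    amp: float,
    rise_scale: float,
    tau: float,
) -> None:
    """Add a logistic-rise / exponential-decay transient in place."""
    n = len(trace)
    i0 = max(0, int((onset - 8 * rise_scale) * frame_rate))
    i1 = min(n, int((onset + 10 * tau) * frame_rate) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / frame_rate
    u = t - onset
    trace[i0:i1] += amp * _logistic(u / rise_scale) * np.exp(-np.maximum(u, 0.0) / tau)


def _add_plateau(
    trace: np.ndarray,
    frame_rate: float,
    rec_time: float,
    amp: float,
    rise_scale: float,
    hold_end: float,
    tau: float,
) -> None:
    """Add a logistic rise, sustained plateau and exponential offset in place."""
    n = len(trace)
    i0 = max(0, int((rec_time - 8 * rise_scale) * frame_rate))
    i1 = min(n, int((hold_end + 10 * tau) * frame_rate) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / frame_rate
    v = amp * _logistic((t - rec_time) / rise_scale)
    v *= np.exp(-np.maximum(t - hold_end, 0.0) / tau)
    trace[i0:i1] += v


def _steepest_slope_time(
    filtered: np.ndarray,
    frame_rate: float,
    around: float,
    lo: float = 0.4,
    hi: float = 1.0,
) -> float:
    """Time of maximum first difference within ``[around - lo, around + hi]``."""
    i0 = max(0, int((around - lo) * frame_rate))
    i1 = min(len(filtered) - 1, int((around + hi) * frame_rate))
    d = np.diff(filtered[i0 : i1 + 1])
    return (i0 + int(np.argmax(d)) + 1) / frame_rate


def _half_max_onset(
    filtered: np.ndarray, frame_rate: float, t_window: tuple[float, float]
) -> float:
    """Upward half-max crossing of the supra-half-max interval peaking in a window.

    The probe is the trace maximum inside ``t_window``; the onset is found by
    walking left to the first sample of the contiguous supra-half-max run.
    """
    half = 0.5 * float(np.max(filtered))
    i0 = max(0, int(t_window[0] * frame_rate))
    i1 = min(len(filtered), int(t_window[1] * frame_rate))
    i = i0 + int(np.argmax(filtered[i0:i1]))
    if filtered[i] < half:
        raise RuntimeError("window peak below half-max (mis-sized config?)")
    while i > 0 and filtered[i - 1] >= half:
        i -= 1
    return i / frame_rate


def _planar_delays(positions: np.ndarray, angle_deg: float, velocity: float) -> np.ndarray:
    theta = np.radians(angle_deg)
    proj = positions[:, 0] * np.cos(theta) + positions[:, 1] * np.sin(theta)
    return (proj - proj.min()) / velocity


def _colored_noise(
    n: int, fs: float, rng: np.random.Generator, exponent: float, band: tuple[float, float]
) -> np.ndarray:
    """Band-limited 1/f^exponent (power) noise, normalized to unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    in_band = (f >= band[0]) & (f <= band[1])
    shape[in_band] = f[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _swd_waveform(fs: float, half_width: float = 0.5) -> np.ndarray:
    """Stereotyped biphasic SWD: sharp spike plus slower after-wave, peak at center."""
    t = np.arange(-half_width, half_width + 0.5 / fs, 1.0 / fs)
    spike = np.exp(-(t**2) / (2 * 0.015**2))
    wave = 0.5 * np.exp(-((t - 0.2) ** 2) / (2 * 0.08**2))
    return spike + wave


def _insert(signal: np.ndarray, waveform: np.ndarray, center_idx: int) -> None:
    half = len(waveform) // 2
    i0, i1 = center_idx - half, center_idx + half + 1
    w0 = max(0, -i0)
    w1 = len(waveform) - max(0, i1 - len(signal))
    i0, i1 = max(i0, 0), min(i1, len(signal))
    if i1 > i0:
        signal[i0:i1] += waveform[w0:w1]


def generate_recording(
    cfg: SimConfig,
) -> tuple[CalciumRecording, EEGRecording, GroundTruth]:
    """Generate a paired calcium + EEG recording and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_frames = int(round(cfg.duration * cfg.frame_rate))
    n_cells = cfg.n_cells
    fr = cfg.frame_rate
    tau = cfg.tau_decay

    positions = rng.uniform(0.0, cfg.field_size, size=(n_cells, 2))

    # --- population pre-ictal spike train (gamma-renewal with refractory gap)
    pis_end = (
        cfg.seizure_onset - cfg.pis_stop_margin if cfg.seizure else cfg.duration - 10.0
    )
    mean_gap = 60.0 / cfg.pis_rate
    gap_excess = max(mean_gap - cfg.pis_min_gap, 0.1)
    onsets = []
    t = cfg.pis_start + rng.uniform(0, mean_gap)
    while t < pis_end:
        onsets.append(t)
        t += cfg.pis_min_gap + rng.gamma(2.0, gap_excess / 2.0)
    pis_onsets = np.asarray(onsets)
    n_pis = len(pis_onsets)

    sentinel_onset = None
    if cfg.seizure and cfg.sentinel:
        sentinel_onset = cfg.seizure_onset - rng.uniform(*cfg.sentinel_lead)

    # participation and per-cell event times/amplitudes
    participation = rng.random((n_cells, n_pis)) < cfg.pis_participation
    cell_onsets = pis_onsets[None, :] + np.clip(
        rng.normal(0.0, cfg.pis_jitter, size=(n_cells, n_pis)), -0.5, 0.5
    )
    amps = cfg.pis_amp * np.exp(
        rng.normal(0.0, cfg.pis_amp_jitter, size=(n_cells, n_pis))
        if cfg.pis_amp_jitter > 0
        else np.zeros((n_cells, n_pis))
    )
    if sentinel_onset is not None:
        sent_cell_onsets = sentinel_onset + np.clip(
            rng.normal(0.0, 0.05, size=n_cells), -0.2, 0.2
        )

    seizure_delays = terminal_delays = None
    sz_participates = term_participates = None
    if cfg.seizure:
        seizure_delays = _planar_delays(positions, cfg.seizure_angle, cfg.seizure_velocity)
        sz_participates = rng.random(n_cells) < cfg.seizure_participation
    if cfg.terminal:
        terminal_delays = _planar_delays(
            positions, cfg.terminal_angle, cfg.terminal_velocity
        )
        term_participates = rng.random(n_cells) < cfg.terminal_participation

    # --- clean per-cell somatic dF/F0
    clean = np.zeros((n_cells, n_frames))
    for i in range(n_cells):
        n_bg = rng.poisson(cfg.background_rate * cfg.duration)
        bg_times = np.sort(rng.uniform(0.0, cfg.duration, size=n_bg))
        bg_amps = cfg.background_amp * rng.uniform(0.5, 1.5, size=n_bg)
        for bt, ba in zip(bg_times, bg_amps):
            _add_transient(clean[i], fr, bt, ba, cfg.rise_time, tau)
        for j in range(n_pis):
            if participation[i, j]:
                _add_transient(clean[i], fr, cell_onsets[i, j], amps[i, j], cfg.rise_time, tau)
        if sentinel_onset is not None:
            _add_transient(clean[i], fr, sent_cell_onsets[i], cfg.sentinel_amp, cfg.rise_time, tau)
        if cfg.seizure and sz_participates[i]:
            _add_plateau(
                clean[i],
                fr,
                cfg.seizure_onset + seizure_delays[i],
                cfg.seizure_amp,
                cfg.seizure_rise_scale,
                cfg.seizure_onset + cfg.seizure_duration + seizure_delays[i],
                tau,
            )
        if cfg.terminal and term_participates[i]:
            _add_plateau(
                clean[i],
                fr,
                cfg.terminal_onset + terminal_delays[i],
                cfg.terminal_amp,
                cfg.terminal_rise_scale,
                cfg.terminal_onset + terminal_delays[i] + cfg.terminal_hold,
                tau,
            )

    # neuropil carries the shared population signal (with mild per-cell gain)
    pop_clean = clean.mean(axis=0)
    neu_gain = rng.uniform(0.9, 1.1, size=n_cells)
    clean_neu = neu_gain[:, None] * pop_clean[None, :]

    # --- raw-fluorescence reconstruction (inverts the normalization pipeline)
    times = np.arange(n_frames) / fr
    bleach = cfg.bleach_end + (1.0 - cfg.bleach_end) * np.exp(-2.0 * times / cfg.duration)
    f0s = cfg.soma_f0 * rng.uniform(1 - cfg.f0_spread, 1 + cfg.f0_spread, size=n_cells)
    f0n = cfg.neuropil_f0 * rng.uniform(1 - cfg.f0_spread, 1 + cfg.f0_spread, size=n_cells)
    b = cfg.background_level

    def to_raw(dff_soma: np.ndarray, dff_neu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        neu_raw = b + f0n[:, None] * (1.0 + dff_neu) * bleach[None, :]
        soma_raw = (
            b
            + f0s[:, None] * (1.0 + dff_soma) * bleach[None, :]
            + cfg.neuropil_coeff * (neu_raw - b)
        )
        return soma_raw, neu_raw

    # --- ground-truth times from the noise-free recording, normalized and
    # filtered exactly as the detectors will see it
    soma_raw_clean, neu_raw_clean = to_raw(clean, clean_neu)
    rec_clean = CalciumRecording(soma_raw_clean, neu_raw_clean, positions, fr)
    norm_clean = preprocess_traces(rec_clean, cfg.neuropil_coeff)
    pop_filt = zero_phase_lowpass(norm_clean.mean_neuropil, fr, cfg.filter_cutoff)

    pis_times = np.array(
        [_steepest_slope_time(pop_filt, fr, t) for t in pis_onsets]
    )
    sentinel_time = None
    if sentinel_onset is not None:
        sentinel_time = _steepest_slope_time(pop_filt, fr, sentinel_onset)
        pis_times = np.append(pis_times, sentinel_time)
        participation = np.column_stack([participation, np.ones(n_cells, dtype=bool)])
        cell_onsets = np.column_stack([cell_onsets, sent_cell_onsets])
    # snap canonical times to the EEG sample grid (they become SWD peaks)
    pis_times = np.round(pis_times * cfg.eeg_fs) / cfg.eeg_fs

    cell_pis_times = np.full(cell_onsets.shape, np.nan)
    cell_seizure_times = cell_terminal_times = None
    cell_seizure_geo = cell_terminal_geo = None
    for i in range(n_cells):
        cell_filt = zero_phase_lowpass(norm_clean.dff_soma[i], fr, cfg.filter_cutoff)
        for j in range(cell_onsets.shape[1]):
            if participation[i, j]:
                cell_pis_times[i, j] = _steepest_slope_time(cell_filt, fr, cell_onsets[i, j])
        if cfg.seizure and sz_participates[i]:
            if cell_seizure_times is None:
                cell_seizure_times = np.full(n_cells, np.nan)
                cell_seizure_geo = np.full(n_cells, np.nan)
            geo = cfg.seizure_onset + seizure_delays[i]
            cell_seizure_geo[i] = geo
            cell_seizure_times[i] = _steepest_slope_time(cell_filt, fr, geo, lo=0.6, hi=0.6)
        if cfg.terminal and term_participates[i]:
            if cell_terminal_times is None:
                cell_terminal_times = np.full(n_cells, np.nan)
                cell_terminal_geo = np.full(n_cells, np.nan)
            geo = cfg.terminal_onset + terminal_delays[i]
            cell_terminal_geo[i] = geo
            cell_terminal_times[i] = _steepest_slope_time(cell_filt, fr, geo, lo=1.0, hi=1.0)

    seizure_seed_time = terminal_seed_time = None
    if cfg.seizure:
        cross = float(np.max(seizure_delays)) if seizure_delays is not None else 0.0
        seizure_seed_time = _half_max_onset(
            pop_filt, fr, (cfg.seizure_onset, cfg.seizure_onset + cross + cfg.seizure_duration)
        )
    if cfg.terminal:
        t_cross = float(np.max(terminal_delays))
        terminal_seed_time = _half_max_onset(
            pop_filt, fr, (cfg.terminal_onset, cfg.terminal_onset + t_cross + cfg.terminal_hold)
        )

    # --- noise and final raw traces
    if cfg.noise_sd_range is not None:
        lo, hi = cfg.noise_sd_range
        noise_sd = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))
    else:
        noise_sd = np.full(n_cells, cfg.noise_sd)
    dff_soma = clean + noise_sd[:, None] * rng.standard_normal((n_cells, n_frames))
    dff_neu = clean_neu + (
        cfg.neuropil_noise_frac * noise_sd[:, None] * rng.standard_normal((n_cells, n_frames))
    )
    if cfg.drift_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_cells)
        dff_soma += cfg.drift_amp * np.sin(
            2 * np.pi * times[None, :] / cfg.drift_period + phases[:, None]
        )
    soma_raw, neu_raw = to_raw(dff_soma, dff_neu)
    recording = CalciumRecording(soma_raw, neu_raw, positions, fr)

    # --- EEG: colored noise + SWD waveforms + ictal rhythmic discharge
    n_eeg = int(round(cfg.duration * cfg.eeg_fs))
    eeg_sig = cfg.eeg_noise * _colored_noise(
        n_eeg, cfg.eeg_fs, rng, cfg.eeg_exponent, (0.5, 300.0)
    )
    rsd = robust_sd(eeg_sig)
    swd = _swd_waveform(cfg.eeg_fs)
    for t_spk in pis_times:
        amp = cfg.sentinel_eeg_amp if (
            sentinel_time is not None and abs(t_spk - sentinel_time) < 1e-9
        ) else cfg.swd_amp
        _insert(eeg_sig, amp * rsd * swd, int(round(t_spk * cfg.eeg_fs)))
    if cfg.seizure and seizure_seed_time is not None:
        i0 = int(seizure_seed_time * cfg.eeg_fs)
        i1 = min(
            n_eeg,
            int((cfg.seizure_onset + cfg.seizure_duration + np.max(seizure_delays) + 2.0) * cfg.eeg_fs),
        )
        tt = np.arange(i1 - i0) / cfg.eeg_fs
        envelope = np.hanning(2 * len(tt))[len(tt):] if len(tt) else np.empty(0)
        eeg_sig[i0:i1] += (
            cfg.ictal_eeg_amp * rsd * np.sin(2 * np.pi * cfg.ictal_eeg_freq * tt) * (0.3 + 0.7 * envelope[::-1])
        )
    eeg = EEGRecording(samples=eeg_sig, fs=cfg.eeg_fs)

    wave_params = {}
    if cfg.seizure:
        wave_params["seizure"] = {
            "onset": cfg.seizure_onset,
            "velocity_um_s": cfg.seizure_velocity,
            "angle_deg": cfg.seizure_angle,
        }
    if cfg.terminal:
        wave_params["terminal"] = {
            "onset": cfg.terminal_onset,
            "velocity_um_s": cfg.terminal_velocity,
            "angle_deg": cfg.terminal_angle,
        }

    truth = GroundTruth(
        pis_times=pis_times,
        participation=participation,
        cell_pis_times=cell_pis_times,
        sentinel_time=sentinel_time,
        seizure_seed_time=seizure_seed_time,
        terminal_seed_time=terminal_seed_time,
        cell_seizure_times=cell_seizure_times,
        cell_terminal_times=cell_terminal_times,
        cell_seizure_times_geo=cell_seizure_geo,
        cell_terminal_times_geo=cell_terminal_geo,
        wave_params=wave_params,
        noise_sd_per_cell=noise_sd,
    )
    return recording, eeg, truth


def export_fixture(
    recording: CalciumRecording,
    eeg: EEGRecording,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a recording, its EEG and ground truth to disk.

    Layout (Suite2p-convention arrays plus plain-text tables):

    - ``F.npy``, ``Fneu.npy``, ``iscell.npy``, ``positions.npy``, ``meta.json``
    - ``eeg.csv`` (columns ``time_s,value``)
    - ``ground_truth_population.csv``, ``ground_truth_cells.csv``, ``wave_params.json``
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    np.save(out / "F.npy", recording.soma_raw)
    np.save(out / "Fneu.npy", recording.neuropil_raw)
    iscell = np.ones((recording.n_cells, 2))
    np.save(out / "iscell.npy", iscell)
    np.save(out / "positions.npy", recording.positions)
    (out / "meta.json").write_text(
        json.dumps(
            {"frame_rate": recording.frame_rate, "t0_offset": recording.t0_offset},
            indent=2,
        )
    )
    for name in ("F.npy", "Fneu.npy", "iscell.npy", "positions.npy", "meta.json"):
        paths[name] = out / name

    eeg_df = pd.DataFrame({"time_s": eeg.times(), "value": eeg.samples})
    eeg_df.to_csv(out / "eeg.csv", index=False, float_format="%.17g")
    paths["eeg.csv"] = out / "eeg.csv"

    pop_rows = [
        {"event_type": "pis", "event_index": j, "time_s": t}
        for j, t in enumerate(truth.pis_times)
    ]
    for name in ("sentinel_time", "seizure_seed_time", "terminal_seed_time"):
        value = getattr(truth, name)
        if value is not None:
            pop_rows.append(
                {"event_type": name.replace("_time", ""), "event_index": 0, "time_s": value}
            )
    pd.DataFrame(pop_rows).to_csv(out / "ground_truth_population.csv", index=False)
    paths["ground_truth_population.csv"] = out / "ground_truth_population.csv"

    cell_rows = []
    n_cells, n_pis = truth.participation.shape
    for i in range(n_cells):
        for j in range(n_pis):
            cell_rows.append(
                {
                    "cell": i,
                    "event_type": "pis",
                    "event_index": j,
                    "participating": bool(truth.participation[i, j]),
                    "time_s": truth.cell_pis_times[i, j],
                    "time_geo_s": np.nan,
                }
            )
        for kind, meas, geo in (
            ("seizure", truth.cell_seizure_times, truth.cell_seizure_times_geo),
            ("terminal", truth.cell_terminal_times, truth.cell_terminal_times_geo),
        ):
            if meas is not None:
                cell_rows.append(
                    {
                        "cell": i,
                        "event_type": kind,
                        "event_index": 0,
                        "participating": bool(np.isfinite(meas[i])),
                        "time_s": meas[i],
                        "time_geo_s": geo[i],
                    }
                )
    pd.DataFrame(cell_rows).to_csv(out / "ground_truth_cells.csv", index=False)
    paths["ground_truth_cells.csv"] = out / "ground_truth_cells.csv"

    (out / "wave_params.json").write_text(json.dumps(truth.wave_params, indent=2))
    paths["wave_params.json"] = out / "wave_params.json"
    return paths
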