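"""Population-level event seeds.

Pre-ictal spike (PIS) times reconciled between the population-mean neuropil
calcium trace and the EEG, plus seizure / terminal-spreading-wave onsets from
the mean neuropil trace.  The resulting seed times anchor the per-cell
recruitment detectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import eeg_events as ee
from .signal_core import positive_slope_segments

logger = logging.getLogger(__name__)

__all__ = [
    "EventSeeds",
    "model_spike_integral",
    "detect_population_spikes",
    "reconcile_with_eeg",
    "detect_wavefronts",
    "detect_event_seeds",
]

PROV_CONCORDANT = "concordant"
PROV_KERNEL = "kernel_recovered"


@dataclass
class EventSeeds:
    """Population event times with provenance flags."""

    pis_times: np.ndarray
    pis_provenance: list[str] = field(default_factory=list)
    seizure_time: float | None = None
    terminal_time: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pis_times = np.asarray(self.pis_times, dtype=float).ravel()
        if not self.pis_provenance:
            self.pis_provenance = [PROV_CONCORDANT] * len(self.pis_times)
        order = np.argsort(self.pis_times, kind="stable")
        self.pis_times = self.pis_times[order]
        self.pis_provenance = [self.pis_provenance[i] for i in order]
        if (
            self.seizure_time is not None
            and self.terminal_time is not None
            and not self.seizure_time < self.terminal_time
        ):
            raise ValueError("seizure_time must precede terminal_time")
        if self.seizure_time is not None and len(self.pis_times):
            if np.any(self.pis_times >= self.seizure_time):
                msg = "PIS time(s) at or after seizure onset"
                self.warnings.append(msg)
                warnings.warn(msg)


def model_spike_integral(trace_sd: float, sigma: float = 0.33) -> float:
    """Area of the Gaussian model spike: height ``trace_sd``, SD ``sigma`` s.

    The model spike represents a typical physiological population spike; its
    area ``trace_sd * sigma * sqrt(2*pi)`` is the threshold against which
    candidate event integrals are compared.
    """
    if trace_sd < 0:
        raise ValueError("trace_sd must be nonnegative")
    return float(trace_sd * sigma * np.sqrt(2.0 * np.pi))


def detect_population_spikes(
    mean_neuropil_filtered: np.ndarray,
    frame_rate: float,
    top_frac: float = 0.15,
    model_sigma: float = 0.33,
    t0_offset: float = 0.0,
    t_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Candidate population calcium-spike times from the filtered mean trace.

    Positive-slope segments are ranked by slope-integral; the top ``top_frac``
    are compared against the model-spike integral (the integral of the trace
    above its segment-start value over the rising segment must reach the
    model area).  Survivors are indexed at their point of steepest slope.

    When ``t_range`` is given, both candidate segments and the trace SD used
    for the model spike are restricted to that time interval (used to keep
    ictal plateaus from corrupting the pre-ictal spike statistics).
    """
    x = np.asarray(mean_neuropil_filtered, dtype=float)
    if t_range is not None:
        i0 = max(0, int(np.ceil((t_range[0] - t0_offset) * frame_rate)))
        i1 = min(len(x), int(np.floor((t_range[1] - t0_offset) * frame_rate)) + 1)
        x = x[i0:i1]
        t0_offset = t0_offset + i0 / frame_rate
    if len(x) < 2:
        return np.empty(0)

    segments = positive_slope_segments(x, frame_rate, t0_offset=t0_offset)
    if not segments:
        return np.empty(0)
    segments.sort(key=lambda s: s.slope_integral, reverse=True)
    n_keep = max(1, int(np.ceil(top_frac * len(segments))))
    retained = segments[:n_keep]

    threshold = model_spike_integral(float(np.std(x)), model_sigma)
    times = []
    for seg in retained:
        rise = x[seg.start_frame : seg.end_frame + 1] - x[seg.start_frame]
        integral = float(np.sum(rise)) / frame_rate
        if integral >= threshold:
            times.append(seg.index_time)
    return np.sort(np.asarray(times))


def reconcile_with_eeg(
    calcium_times: np.ndarray,
    eeg_spikes: ee.EEGSpikeSet,
    tol: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one nearest pairing of calcium candidates with EEG spikes.

    Pairs are formed greedily by ascending absolute time difference; only
    pairs within ``tol`` seconds are accepted, and each paired event
    contributes the EEG time.  Returns the paired EEG times (sorted) and the
    indices of the matched EEG spikes.
    """
    calcium_times = np.asarray(calcium_times, dtype=float).ravel()
    if len(eeg_spikes) == 0:
        warnings.warn("empty EEG spike set: no PIS can be reconciled")
        return np.empty(0), np.empty(0, dtype=int)
    if len(calcium_times) == 0:
        return np.empty(0), np.empty(0, dtype=int)

    pairs = [
        (abs(ct - et), ci, ei)
        for ci, ct in enumerate(calcium_times)
        for ei, et in enumerate(eeg_spikes.times)
        if abs(ct - et) <= tol
    ]
    pairs.sort()
    used_c: set[int] = set()
    used_e: set[int] = set()
    matched_e: list[int] = []
    for _, ci, ei in pairs:
        if ci in used_c or ei in used_e:
            continue
        used_c.add(ci)
        used_e.add(ei)
        matched_e.append(ei)
    matched_e.sort()
    return eeg_spikes.times[matched_e], np.asarray(matched_e, dtype=int)


def detect_wavefronts(
    mean_neuropil_filtered: np.ndarray,
    frame_rate: float,
    t0_offset: float = 0.0,
) -> tuple[float | None, float | None, list[str]]:
    """Seizure and terminal-spreading-wave onset from the filtered mean trace.

    Contiguous intervals above half of the global maximum are scored by the
    integral of the trace over the interval; the two largest are the seizure
    (earlier) and terminal wave (later), each indexed at its first upward
    half-max crossing.  Fewer than two supra-half-max intervals returns what
    exists with a warning (fatal-seizure truncation case).
    """
    x = np.asarray(mean_neuropil_filtered, dtype=float)
    warns: list[str] = []
    if len(x) < 2 or not np.any(np.isfinite(x)):
        return None, None, ["empty or non-finite trace"]
    half = 0.5 * float(np.nanmax(x))
    above = x >= half
    if not above.any():
        return None, None, ["no supra-half-max interval found"]

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]

    intervals = [(s, e, float(np.sum(x[s:e])) / frame_rate) for s, e in zip(starts, ends)]
    intervals.sort(key=lambda it: it[2], reverse=True)
    top = sorted(intervals[:2], key=lambda it: it[0])  # tie and order by time

    def onset(iv) -> float:
        return t0_offset + iv[0] / frame_rate

    if len(top) == 1:
        msg = "only one supra-half-max event: terminal wave absent (truncated recording?)"
        warnings.warn(msg)
        warns.append(msg)
        return onset(top[0]), None, warns
    return onset(top[0]), onset(top[1]), warns


def detect_event_seeds(
    mean_neuropil_filtered: np.ndarray,
    frame_rate: float,
    eeg: ee.EEGRecording,
    *,
    t0_offset: float = 0.0,
    top_frac: float = 0.15,
    model_sigma: float = 0.33,
    eeg_k_sd: float = 4.5,
    eeg_min_separation: float = 0.7,
    ratio_min: float = 20.0,
    isi_min: float = 0.7,
    reconcile_tol: float = 0.2,
    kernel_half_width: float = 0.5,
    recover_k_sd: float = 5.0,
    recover_min_separation: float = 1.0,
    preictal_buffer: float = 2.0,
    detect_waves: bool = True,
) -> EventSeeds:
    """Full population-seed pipeline: wavefronts, then EEG-reconciled PIS.

    Wavefront onsets are detected first; when a seizure is found, PIS
    detection (calcium candidates, the trace SD feeding the model-spike
    threshold, and kernel-recovered EEG spikes) is restricted to the
    pre-ictal period ending ``preictal_buffer`` seconds before seizure onset,
    since pre-ictal spikes are by definition pre-ictal and ictal activity
    corrupts both statistics.
    """
    warns: list[str] = []
    seizure_time = terminal_time = None
    if detect_waves:
        seizure_time, terminal_time, w = detect_wavefronts(
            mean_neuropil_filtered, frame_rate, t0_offset
        )
        warns.extend(w)

    t_end = t0_offset + len(mean_neuropil_filtered) / frame_rate
    if seizure_time is not None:
        t_end = min(t_end, seizure_time - preictal_buffer)
    t_range = (t0_offset, t_end)

    # EEG candidates -> spectral exclusion, restricted to the pre-ictal period
    eeg_spikes = ee.detect_eeg_spikes_threshold(eeg, eeg_k_sd, eeg_min_separation)
    eeg_spikes = ee.spectral_ratio_filter(eeg, eeg_spikes, ratio_min, isi_min)
    in_range = (eeg_spikes.times >= t_range[0]) & (eeg_spikes.times <= t_range[1])
    eeg_spikes = ee.EEGSpikeSet(
        times=eeg_spikes.times[in_range],
        sources=[s for s, m in zip(eeg_spikes.sources, in_range) if m],
    )

    calcium_times = detect_population_spikes(
        mean_neuropil_filtered,
        frame_rate,
        top_frac=top_frac,
        model_sigma=model_sigma,
        t0_offset=t0_offset,
        t_range=t_range,
    )
    pis_times, _ = reconcile_with_eeg(calcium_times, eeg_spikes, reconcile_tol)
    provenance = [PROV_CONCORDANT] * len(pis_times)

    # matched-kernel recovery of missed low-amplitude spikes
    if len(pis_times):
        try:
            kernel = ee.build_swd_kernel(eeg, pis_times, kernel_half_width)
            concordant = ee.EEGSpikeSet(times=pis_times, sources=list(provenance))
            recovered = ee.recover_missed_spikes(
                eeg, kernel, concordant, recover_k_sd, recover_min_separation
            )
            for t, src in zip(recovered.times, recovered.sources):
                if src == ee.SOURCE_KERNEL and t_range[0] <= t <= t_range[1]:
                    pis_times = np.append(pis_times, t)
                    provenance.append(PROV_KERNEL)
        except ValueError as exc:
            msg = f"SWD kernel recovery skipped: {exc}"
            logger.warning(msg)
            warns.append(msg)
    else:
        msg = "no concordant PIS: kernel recovery skipped"
        logger.warning(msg)
        warns.append(msg)

    return EventSeeds(
        pis_times=pis_times,
        pis_provenance=provenance,
        seizure_time=seizure_time,
        terminal_time=terminal_time,
        warnings=warns,
    )
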