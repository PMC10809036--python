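"""Seed-guided per-cell recruitment detection.

Given population-level seed times, decide for each cell whether (and when)
it was recruited into each pre-ictal spike, the seizure wavefront, and the
terminal spreading wave.  Recruitment times are points of steepest slope of
the cell's filtered dF/F0 trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import SlopeSegment, positive_slope_segments

__all__ = [
    "RecruitmentResult",
    "GaussianSeedWeight",
    "preictal_stats",
    "detect_cell_pis",
    "detect_cell_wavefront",
]

EVENT_PIS = "pis"
EVENT_SEIZURE = "seizure"
EVENT_TERMINAL = "terminal"

# per-event-type defaults: (gaussian sigma s, before/after window s, seed tolerance s)
WAVEFRONT_PARAMS = {
    EVENT_SEIZURE: (1.0, 10.0, 3.0),
    EVENT_TERMINAL: (5.0, 5.0, 5.0),
}


@dataclass
class RecruitmentResult:
    """Per cell x event recruitment decision."""

    cell_index: int
    event_type: str
    event_seed_time: float
    recruited: bool
    recruitment_time: float | None = None
    feature: float | None = None
    criterion_value: float | None = None


@dataclass
class GaussianSeedWeight:
    """Gaussian weight of temporal distance from a seed time."""

    center: float
    sigma: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-0.5 * ((np.asarray(t) - self.center) / self.sigma) ** 2)


def preictal_stats(
    trace: np.ndarray,
    frame_rate: float,
    seizure_time: float | None,
    t0_offset: float = 0.0,
    margin: float = 10.0,
) -> tuple[float, float]:
    """Mean and SD of a trace over its pre-ictal portion.

    The portion runs from the start of the recording to ``seizure_time -
    margin`` (full trace when no seizure is known); ictal plateaus would
    otherwise inflate the SD used by the 4-sigma peak criterion.
    """
    x = np.asarray(trace, dtype=float)
    if seizure_time is not None:
        n = int((seizure_time - margin - t0_offset) * frame_rate)
        if n >= int(2 * frame_rate):  # need a nontrivial window
            x = x[:n]
    return float(np.mean(x)), float(np.std(x))


def detect_cell_pis(
    cell_dff_filtered: np.ndarray,
    frame_rate: float,
    pis_seeds: np.ndarray,
    *,
    cell_index: int = 0,
    seizure_time: float | None = None,
    top_frac: float = 0.20,
    tol: float = 1.5,
    peak_z: float = 4.0,
    t0_offset: float = 0.0,
    stats_margin: float = 10.0,
) -> list[RecruitmentResult]:
    """Per-cell pre-ictal spike recruitment for each seed time.

    Slope segments are ranked by slope-integral and the top ``top_frac``
    retained.  Each seed's candidate is the retained segment with steepest-
    slope time nearest the seed (one segment serves at most one seed; the
    nearest seed wins on conflict).  A cell is recruited when the candidate
    lies within ``tol`` seconds of the seed and the segment peak exceeds the
    cell's pre-ictal mean by more than ``peak_z`` SDs.
    """
    pis_seeds = np.asarray(pis_seeds, dtype=float).ravel()
    results = [
        RecruitmentResult(cell_index, EVENT_PIS, float(seed), False) for seed in pis_seeds
    ]
    if len(pis_seeds) == 0:
        return results

    segments = positive_slope_segments(
        cell_dff_filtered, frame_rate, t0_offset=t0_offset, cell_index=cell_index
    )
    if not segments:
        return results
    segments.sort(key=lambda s: s.slope_integral, reverse=True)
    n_keep = max(1, int(np.ceil(top_frac * len(segments))))
    retained = segments[:n_keep]

    mean, sd = preictal_stats(
        cell_dff_filtered, frame_rate, seizure_time, t0_offset, stats_margin
    )

    # globally greedy one-to-one assignment by ascending |dt|
    pairs = sorted(
        (abs(seg.index_time - seed), si, gi)
        for si, seed in enumerate(pis_seeds)
        for gi, seg in enumerate(retained)
    )
    used_seeds: set[int] = set()
    used_segs: set[int] = set()
    for dt, si, gi in pairs:
        if si in used_seeds or gi in used_segs:
            continue
        used_seeds.add(si)
        used_segs.add(gi)
        seg = retained[gi]
        z = (seg.peak_value - mean) / sd if sd > 0 else np.inf
        res = results[si]
        res.feature = seg.slope_integral
        res.criterion_value = float(z)
        res.recruitment_time = seg.index_time
        res.recruited = bool(dt <= tol and z > peak_z)
        if not res.recruited:
            res.recruitment_time = None
    return results


def detect_cell_wavefront(
    cell_dff_filtered: np.ndarray,
    frame_rate: float,
    seed: float,
    kind: str,
    *,
    cell_index: int = 0,
    sigma: float | None = None,
    window: float | None = None,
    tol: float | None = None,
    increase: float = 1.2,
    t0_offset: float = 0.0,
) -> RecruitmentResult:
    """Per-cell seizure-wavefront or terminal-wave recruitment.

    Slope-integral features are weighted by a Gaussian of the distance between
    each segment's steepest-slope time and the seed (sigma 1 s for the seizure
    wavefront so the nearby sentinel spike is suppressed, 5 s for the slower
    terminal wave).  The max-weighted segment gives the recruitment time; the
    cell is recruited when the mean signal over ``window`` seconds after that
    time is at least ``increase`` times the mean over ``window`` seconds
    before it, and the time is within ``tol`` of the seed.
    """
    if kind not in WAVEFRONT_PARAMS:
        raise ValueError(f"kind must be one of {sorted(WAVEFRONT_PARAMS)}")
    d_sigma, d_window, d_tol = WAVEFRONT_PARAMS[kind]
    sigma = d_sigma if sigma is None else sigma
    window = d_window if window is None else window
    tol = d_tol if tol is None else tol

    result = RecruitmentResult(cell_index, kind, float(seed), False)
    x = np.asarray(cell_dff_filtered, dtype=float)
    segments = positive_slope_segments(
        x, frame_rate, t0_offset=t0_offset, cell_index=cell_index
    )
    if not segments:
        return result

    weight = GaussianSeedWeight(center=float(seed), sigma=sigma)
    weighted = [seg.slope_integral * float(weight(seg.index_time)) for seg in segments]
    best: SlopeSegment = segments[int(np.argmax(weighted))]

    rec_frame = best.index_frame
    w = int(round(window * frame_rate))
    before = x[max(0, rec_frame - w) : rec_frame]
    after = x[rec_frame : rec_frame + w]
    if len(before) == 0 or len(after) == 0:
        return result
    mean_before = float(np.mean(before))
    mean_after = float(np.mean(after))

    result.feature = best.slope_integral
    result.criterion_value = mean_after / mean_before if mean_before != 0 else np.inf
    result.recruitment_time = best.index_time
    result.recruited = bool(
        mean_after >= increase * mean_before and abs(best.index_time - seed) <= tol
    )
    if not result.recruited:
        result.recruitment_time = None
    return result
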