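"""Shared signal substrate: trace normalization, zero-phase low-pass filtering,
and extraction of positive-slope segments with the slope-integral feature.

All detectors in this package operate on the outputs of this module.  Traces
are ``cells x frames`` arrays; frame ``i`` maps to time ``t0_offset + i /
frame_rate`` in seconds on the shared EEG clock (0-based frames).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumRecording",
    "NormalizedTraces",
    "SlopeSegment",
    "preprocess_traces",
    "zero_phase_lowpass",
    "positive_slope_segments",
]


@dataclass
class CalciumRecording:
    """Raw per-ROI somatic and neuropil fluorescence with ROI geometry.

    Parameters
    ----------
    soma_raw, neuropil_raw : ndarray, shape (n_cells, n_frames)
        Raw fluorescence in arbitrary units.
    positions : ndarray, shape (n_cells, 2)
        ROI centroid ``(x, y)`` coordinates in micrometers.
    frame_rate : float
        Imaging frame rate in Hz.
    t0_offset : float
        Time of frame 0 in seconds, relative to the EEG trigger clock.
    """

    soma_raw: np.ndarray
    neuropil_raw: np.ndarray
    positions: np.ndarray
    frame_rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.soma_raw = np.asarray(self.soma_raw, dtype=float)
        self.neuropil_raw = np.asarray(self.neuropil_raw, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.soma_raw.ndim != 2:
            raise ValueError("soma_raw must be a 2-D cells x frames array")
        if self.soma_raw.shape != self.neuropil_raw.shape:
            raise ValueError("soma_raw and neuropil_raw must have the same shape")
        if len(self.positions) != self.soma_raw.shape[0]:
            raise ValueError("positions length must equal cell count")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_cells(self) -> int:
        return self.soma_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.soma_raw.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def frame_times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_frames) / self.frame_rate


@dataclass
class NormalizedTraces:
    """Normalized (dF/F0) traces plus normalization bookkeeping."""

    dff_soma: np.ndarray
    dff_neuropil: np.ndarray
    mean_neuropil: np.ndarray
    valid_cells: np.ndarray
    frame_rate: float
    t0_offset: float = 0.0
    background: float = 0.0
    f0_soma: np.ndarray | None = None
    f0_neuropil: np.ndarray | None = None
    filtered: bool = False
    cutoff_hz: float | None = None
    filter_orders: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.dff_soma.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff_soma.shape[1]

    def frame_times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_frames) / self.frame_rate


@dataclass
class SlopeSegment:
    """A maximal run of consecutive frames with positive first difference.

    ``slope_integral`` is the sum of the positive first differences over the
    run, which telescopes to ``trace[end_frame] - trace[start_frame]`` (the
    net rise).  ``index_time`` marks the point of steepest slope.
    """

    cell_index: int | str
    start_frame: int
    end_frame: int
    slope_integral: float
    index_frame: int
    index_time: float
    peak_value: float


def preprocess_traces(
    rec: CalciumRecording,
    neuropil_coeff: float = 0.7,
    baseline_window: float = 30.0,
) -> NormalizedTraces:
    """Background-subtract, neuropil-correct and dF/F0-normalize raw traces.

    The background is a single scalar: the global minimum over all neuropil
    samples.  The corrected somatic signal is
    ``(soma - b) - neuropil_coeff * (neuropil - b)``, and dF/F0 uses the mean
    of the corrected trace over the first ``baseline_window`` seconds as F0.
    Neuropil dF/F0 is computed analogously without the somatic subtraction.

    Cells whose F0 is not positive are flagged invalid (``valid_cells``) and
    their dF/F0 set to NaN; downstream detectors skip them.
    """
    if not (0.0 <= neuropil_coeff < 1.0):
        raise ValueError("neuropil_coeff must be in [0, 1)")
    n_base = int(round(baseline_window * rec.frame_rate))
    if rec.n_frames <= n_base:
        raise ValueError("recording must be longer than the baseline window")

    b = float(np.min(rec.neuropil_raw))
    soma_corr = (rec.soma_raw - b) - neuropil_coeff * (rec.neuropil_raw - b)
    neu_corr = rec.neuropil_raw - b

    f0_soma = soma_corr[:, :n_base].mean(axis=1)
    f0_neu = neu_corr[:, :n_base].mean(axis=1)

    valid = f0_soma > 0
    valid_neu = f0_neu > 0
    if not np.all(valid):
        logger.warning(
            "excluding %d cell(s) with non-positive baseline F0", int((~valid).sum())
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        dff_soma = soma_corr / f0_soma[:, None] - 1.0
        dff_neu = neu_corr / f0_neu[:, None] - 1.0
    dff_soma[~valid] = np.nan
    dff_neu[~valid_neu] = np.nan

    if valid_neu.any():
        mean_neuropil = np.nanmean(dff_neu[valid_neu], axis=0)
    else:
        mean_neuropil = np.full(rec.n_frames, np.nan)

    return NormalizedTraces(
        dff_soma=dff_soma,
        dff_neuropil=dff_neu,
        mean_neuropil=mean_neuropil,
        valid_cells=valid,
        frame_rate=rec.frame_rate,
        t0_offset=rec.t0_offset,
        background=b,
        f0_soma=f0_soma,
        f0_neuropil=f0_neu,
    )


def zero_phase_lowpass(
    trace: np.ndarray,
    frame_rate: float,
    cutoff: float = 1.0,
    order_range: tuple[int, int] = (3, 5),
    return_order: bool = False,
):
    """Forward-backward (zero net phase) Butterworth low-pass filter.

    The order is chosen adaptively: the highest order in ``order_range`` is
    tried first; if the output contains non-finite values or its energy
    exceeds the input's by more than 1% (instability), the order is
    decremented.  The order actually used is logged.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if not cutoff < frame_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    lo, hi = int(min(order_range)), int(max(order_range))
    if len(x) <= 3 * hi:
        raise ValueError("trace too short for the requested filter order")

    energy_in = float(np.sum(x**2))
    last_exc: Exception | None = None
    for order in range(hi, lo - 1, -1):
        sos = sps.butter(order, cutoff, btype="low", fs=frame_rate, output="sos")
        try:
            y = sps.sosfiltfilt(sos, x)
        except ValueError as exc:  # padlen issues on short traces
            last_exc = exc
            continue
        stable = np.all(np.isfinite(y)) and float(np.sum(y**2)) <= 1.01 * energy_in + 1e-12
        if stable:
            logger.debug("zero_phase_lowpass: used order %d", order)
            return (y, order) if return_order else y
    if last_exc is not None:
        raise ValueError(f"filtering failed: {last_exc}")
    raise ValueError("no stable filter order found in order_range")


def positive_slope_segments(
    filtered_trace: np.ndarray,
    frame_rate: float,
    t0_offset: float = 0.0,
    cell_index: int | str = "population",
) -> list[SlopeSegment]:
    """Isolate maximal positive-slope runs and their slope-integral features.

    The first derivative is the forward first difference; "positive slope"
    means a strictly positive difference.  Each segment is indexed at its
    point of steepest slope (frame following the maximum first difference).
    """
    x = np.asarray(filtered_trace, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("filtered_trace must be 1-D with length >= 2")
    d = np.diff(x)
    pos = d > 0
    if not pos.any():
        return []

    # boundaries of runs of consecutive True in `pos`
    edges = np.diff(pos.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if pos[0]:
        starts = np.r_[0, starts]
    if pos[-1]:
        ends = np.r_[ends, len(pos)]

    segments: list[SlopeSegment] = []
    for s, e in zip(starts, ends):
        # diffs d[s:e] are all positive; frames covered are s .. e
        run = d[s:e]
        # first index attaining the maximum (within float tolerance)
        idx = s + int(np.flatnonzero(run >= run.max() - 1e-12)[0]) + 1
        segments.append(
            SlopeSegment(
                cell_index=cell_index,
                start_frame=int(s),
                end_frame=int(e),
                slope_integral=float(run.sum()),
                index_frame=idx,
                index_time=t0_offset + idx / frame_rate,
                peak_value=float(x[e]),
            )
        )
    return segments
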