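"""Detection-performance evaluation.

Tolerance-based event matching, accuracy and F1, a simulated-Poisson chance
baseline, the pre-ictal SNR metric, and the SNR-versus-performance
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "MatchCounts",
    "SNRRecord",
    "RegressionResult",
    "match_events",
    "accuracy",
    "f1",
    "poisson_baseline",
    "compute_snr",
    "snr_performance_regression",
    "bootstrap_ci",
]


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class SNRRecord:
    cell_index: int
    snr: float  # NaN when undefined
    n_peaks: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.snr)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def match_events(
    manual: np.ndarray, detected: np.ndarray, tol: float = 1.0
) -> MatchCounts:
    """Match detections to manual labels within a time tolerance.

    Manual events are iterated chronologically; each is matched to the
    nearest unused detected event within ``tol`` seconds (ties resolved to
    the earlier detection).  Unmatched manual events count as false
    negatives, unmatched detections as false positives.
    """
    manual = np.sort(np.asarray(manual, dtype=float).ravel())
    detected = np.sort(np.asarray(detected, dtype=float).ravel())
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for m in manual:
        free = np.flatnonzero(~used)
        if len(free) == 0:
            break
        dts = np.abs(detected[free] - m)
        j = free[int(np.argmin(dts))]  # argmin tie -> earlier detection
        if abs(detected[j] - m) <= tol:
            used[j] = True
            tp += 1
    fn = len(manual) - tp
    fp = int((~used).sum())
    return MatchCounts(tp=tp, fp=fp, fn=fn)


def accuracy(c: MatchCounts) -> float:
    """``TP / (TP + FP + FN)``."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return c.tp / denom


def f1(c: MatchCounts, variant: str = "geometric") -> float:
    """F1 score from match counts.

    ``variant='geometric'`` (default) returns ``sqrt(recall * precision)``;
    ``variant='product'`` returns ``recall * precision``.
    """
    if c.tp + c.fp + c.fn == 0:
        raise ValueError("f1 undefined for all-zero counts")
    if c.tp == 0:
        return 0.0
    prod = c.recall * c.precision
    if variant == "geometric":
        return float(np.sqrt(prod))
    if variant == "product":
        return float(prod)
    raise ValueError("variant must be 'geometric' or 'product'")


def poisson_baseline(
    manual: np.ndarray,
    duration: float,
    n_reps: int = 50,
    tol: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Chance-level F1 from a rate-matched homogeneous Poisson process.

    The Poisson rate is the manual event count divided by ``duration``; per
    repetition, random event times are matched against the manual labels and
    the mean F1 over repetitions is returned.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    manual = np.asarray(manual, dtype=float).ravel()
    if len(manual) == 0:
        return 0.0
    rng = np.random.default_rng(rng)
    lam = len(manual) / duration
    scores = []
    for _ in range(n_reps):
        n = rng.poisson(lam * duration)
        detected = np.sort(rng.uniform(0.0, duration, size=n))
        scores.append(f1(match_events(manual, detected, tol)))
    return float(np.mean(scores))


def compute_snr(
    cell_dff: np.ndarray,
    preictal_window: tuple[int, int] | None = None,
    prominence_min: float = 1.0,
    *,
    cell_index: int = 0,
) -> SNRRecord:
    """Pre-ictal signal-to-noise ratio of a cell's dF/F0 trace.

    Signal: mean height (dF/F0 value) of local maxima with topographic
    prominence above ``prominence_min`` within the pre-ictal window.  Noise:
    the 40th-minus-10th-percentile spread of the windowed series, which
    excludes outliers and the peaks themselves.  NaN when no qualifying peak
    exists or the spread is zero (cell excluded from the SNR regression).
    """
    x = np.asarray(cell_dff, dtype=float).ravel()
    if preictal_window is not None:
        x = x[preictal_window[0] : preictal_window[1]]
    if len(x) == 0:
        raise ValueError("pre-ictal window is empty")
    # strict "greater than" threshold (find_peaks keeps prominence >= value)
    peaks, _ = sps.find_peaks(x, prominence=prominence_min * (1 + 1e-12) + 1e-300)
    if len(peaks) == 0:
        return SNRRecord(cell_index, np.nan, 0)
    spread = float(np.percentile(x, 40) - np.percentile(x, 10))
    if spread <= 0:
        return SNRRecord(cell_index, np.nan, len(peaks))
    return SNRRecord(cell_index, float(np.mean(x[peaks])) / spread, len(peaks))


def snr_performance_regression(
    per_cell_f1: np.ndarray, per_cell_snr: np.ndarray
) -> RegressionResult:
    """Ordinary least-squares fit of per-cell F1 on per-cell SNR."""
    y = np.asarray(per_cell_f1, dtype=float).ravel()
    x = np.asarray(per_cell_snr, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("per_cell_f1 and per_cell_snr must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate SNR variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def bootstrap_ci(
    values: np.ndarray,
    statistic=np.median,
    n_boot: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of a statistic across cells."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite values")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = np.apply_along_axis(statistic, 1, values[idx])
    return (
        float(np.percentile(boots, 100 * alpha / 2)),
        float(np.percentile(boots, 100 * (1 - alpha / 2))),
    )
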