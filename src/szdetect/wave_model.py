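"""Traveling-wave propagation model.

Per-cell recruitment times are regressed on ROI positions as a plane
``t ~ b0 + bx*x + by*y`` with an optional L1 penalty on the gradient.  The
gradient direction is the propagation direction (times increase along it)
and the propagation speed is the reciprocal gradient norm.  Significance is
assessed by refitting spatially shuffled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveFit", "fit_plane", "shuffle_test"]


@dataclass
class WaveFit:
    beta0: float
    gradient: tuple[float, float]  # seconds / micrometer
    velocity: float  # micrometers / second (NaN when gradient is zero)
    angle: float  # degrees CCW from +x, in [0, 360)
    residual_rss: float
    n_cells: int
    l1_lambda: float
    p_value: float = np.nan


def _design(times: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float).ravel()
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("positions must be an (n, 2) array")
    if len(t) != len(xy):
        raise ValueError("times and positions must have equal length")
    ok = np.isfinite(t) & np.all(np.isfinite(xy), axis=1)
    t, xy = t[ok], xy[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 recruited cells with finite times")
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("positions are collinear: plane fit is degenerate")
    return t, xy


def _solve(t: np.ndarray, xy: np.ndarray, lam: float) -> tuple[float, np.ndarray, float]:
    if lam == 0:
        design = np.column_stack([np.ones(len(t)), xy])
        coef, *_ = np.linalg.lstsq(design, t, rcond=None)
        beta0, grad = float(coef[0]), coef[1:]
    else:
        from sklearn.linear_model import Lasso

        # Lasso objective: (1/2n)||t - Xw - c||^2 + alpha*||w||_1, intercept
        # unpenalized; alpha = lam/2 matches MSE + lam*L1.
        model = Lasso(alpha=lam / 2.0, fit_intercept=True, max_iter=100000, tol=1e-10)
        model.fit(xy, t)
        beta0, grad = float(model.intercept_), np.asarray(model.coef_, dtype=float)
    resid = t - beta0 - xy @ grad
    return beta0, grad, float(np.sum(resid**2))


def _auto_lambda(t: np.ndarray, xy: np.ndarray) -> float:
    if len(t) < 10:
        return 0.0
    from sklearn.linear_model import LassoCV

    model = LassoCV(
        alphas=np.logspace(-8, 0, 25), cv=5, fit_intercept=True, max_iter=100000
    )
    model.fit(xy, t)
    return 2.0 * float(model.alpha_)


def fit_plane(
    times: np.ndarray,
    positions: np.ndarray,
    l1_lambda: float | str = 0.0,
) -> WaveFit:
    """Fit recruitment times to a spatial plane.

    ``l1_lambda`` is the L1 penalty weight on the gradient (intercept
    unpenalized); ``"auto"`` selects it by 5-fold cross-validation over a
    logarithmic grid, falling back to 0 when fewer than 10 cells are
    available.  Angle is measured counter-clockwise from the +x axis of the
    position coordinates (convert image y-down pixel coordinates before
    calling if a standard math convention is wanted).
    """
    t, xy = _design(times, positions)
    lam = _auto_lambda(t, xy) if l1_lambda == "auto" else float(l1_lambda)
    beta0, grad, rss = _solve(t, xy, lam)

    gnorm = float(np.hypot(*grad))
    if gnorm < 1e-12:  # numerically zero gradient: no spatial structure
        velocity = np.nan
        angle = np.nan
        p_value = 1.0
    else:
        velocity = 1.0 / gnorm
        angle = float(np.degrees(np.arctan2(grad[1], grad[0])) % 360.0)
        p_value = np.nan
    return WaveFit(
        beta0=beta0,
        gradient=(float(grad[0]), float(grad[1])),
        velocity=velocity,
        angle=angle,
        residual_rss=rss,
        n_cells=len(t),
        l1_lambda=lam,
        p_value=p_value,
    )


def shuffle_test(
    times: np.ndarray,
    positions: np.ndarray,
    n_shuffles: int = 1000,
    l1_lambda: float = 0.0,
    rng: np.random.Generator | int | None = None,
    observed_rss: float | None = None,
) -> float:
    """Spatial-shuffle significance of a plane fit.

    Times are permuted across positions ``n_shuffles`` times and refit with
    the same penalty; ``p = (1 + #{shuffled RSS <= observed}) / (1 + n)``.
    """
    t, xy = _design(times, positions)
    lam = float(l1_lambda)
    if observed_rss is None:
        observed_rss = _solve(t, xy, lam)[2]
    rng = np.random.default_rng(rng)
    n_le = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(t))
        rss = _solve(t[perm], xy, lam)[2]
        if rss <= observed_rss:
            n_le += 1
    return (1 + n_le) / (1 + n_shuffles)
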