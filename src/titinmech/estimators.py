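"""Measurement procedures turning force-clamp transients into model parameters.

These reproduce the tangent/back-extrapolation analysis applied to the
experimental records: phase-1 and phase-2 amplitudes (``L1``, ``L2``) are the
values, at the half-time of the force step, of straight lines fitted to the
appropriate portion of the length trace; velocities (``Vi``, ``V3``,
``Vsh``) are tangent slopes over documented windows.  Linear relations
(amplitude or velocity vs step size, fluidity vs sarcomere length) are
fitted by ordinary least squares, either pooled or as the average of
per-fiber fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .mech_model import ForceStepProtocol, Transient

__all__ = [
    "StepEstimates",
    "LinearFit",
    "EstimationError",
    "EstimationWarning",
    "estimate_Vi",
    "estimate_L1",
    "estimate_L2",
    "estimate_Vsh",
    "estimate_step_response",
    "fit_relation",
    "fit_fluidity_vs_SL",
    "compare_groups",
]

#: default tangent windows, s (offsets from the end of the force ramp)
VI_WINDOW = 0.5e-3
L1_WINDOW = 0.1e-3
L2_WINDOW_ON = (0.100, 0.200)
L2_WINDOW_OFF = (0.150, 0.250)
VSH_WINDOW = (1e-3, 5e-3)


class EstimationError(ValueError):
    """A tangent/fit window cannot be evaluated on the given record."""


class EstimationWarning(UserWarning):
    """The estimate is returned but its window assumptions are doubtful."""


@dataclass
class StepEstimates:
    """Per-record derived quantities with the windows used."""

    delta_T: float
    SL0: float
    state: str
    L1: Optional[float] = None
    L2: Optional[float] = None
    Vi: Optional[float] = None
    V3: Optional[float] = None
    Vsh: Optional[float] = None
    windows: dict = field(default_factory=dict)
    fiber: Optional[str] = None


@dataclass
class LinearFit:
    """Ordinary least-squares line with standard errors.

    ``abscissa_intercept`` is ``-intercept/slope`` with its standard error
    propagated from the fit covariance.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    n_points: int
    abscissa_intercept: float
    abscissa_intercept_se: float
    mode: str = "pooled"


def _line_over_window(
    t: np.ndarray, x: np.ndarray, t_a: float, t_b: float, min_points: int = 2
) -> tuple[float, float]:
    """Least-squares slope and intercept of ``x(t)`` over ``[t_a, t_b]``."""
    mask = (t >= t_a - 1e-12) & (t <= t_b + 1e-12)
    if int(mask.sum()) < min_points:
        raise EstimationError(
            f"window [{t_a}, {t_b}] s contains {int(mask.sum())} samples "
            f"(need >= {min_points})"
        )
    tw, xw = t[mask], x[mask]
    if np.ptp(tw) == 0:
        raise EstimationError("degenerate window: zero time span")
    slope, intercept = np.polyfit(tw, xw, 1)
    return float(slope), float(intercept)


def estimate_Vi(
    transient: Transient, protocol: ForceStepProtocol, window: float = VI_WINDOW
) -> float:
    """Initial lengthening velocity: tangent slope over the first ``window``
    (default 0.5 ms) of the length response following the step end, nm/s."""
    t_a = protocol.t_end
    t_b = t_a + window
    if transient.time[-1] < t_b - 1e-12:
        raise EstimationError("record ends before the Vi window")
    slope, _ = _line_over_window(transient.time, transient.x, t_a, t_b)
    return slope


def estimate_L1(
    transient: Transient, protocol: ForceStepProtocol, window: float = L1_WINDOW
) -> float:
    """Phase-1 amplitude: the early phase-2 tangent (default first 0.1 ms
    after the step end) back-extrapolated to the step half-time, nm."""
    t_a = protocol.t_end
    slope, intercept = _line_over_window(transient.time, transient.x, t_a, t_a + window)
    return slope * protocol.t_half + intercept


def estimate_L2(
    transient: Transient,
    protocol: ForceStepProtocol,
    fit_window: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Phase-2 amplitude and phase-3 slope.

    Fits a line to the length trace over ``fit_window`` (absolute times;
    default 100–200 ms after the step end for ON records, 150–250 ms for
    OFF records) and back-extrapolates it to the step half-time.

    Returns
    -------
    (L2, V3) : tuple of float
        Back-extrapolated amplitude (nm) and the tangent slope (nm/s, the
        steady lengthening velocity for ON records).
    """
    if fit_window is None:
        lo, hi = L2_WINDOW_ON if transient.state == "ON" else L2_WINDOW_OFF
        fit_window = (protocol.t_end + lo, protocol.t_end + hi)
    t_a, t_b = fit_window
    if t_a < protocol.t_end + 2e-3:
        warnings.warn(
            "phase-3 window begins before phase 2 is expected to be complete",
            EstimationWarning,
            stacklevel=2,
        )
    slope, intercept = _line_over_window(transient.time, transient.x, t_a, t_b)
    return slope * protocol.t_half + intercept, slope


def estimate_Vsh(
    transient: Transient,
    protocol: ForceStepProtocol,
    window: tuple[float, float] = VSH_WINDOW,
) -> float:
    """Shortening velocity after a negative step, nm/s (negative).

    The tangent window (default 1–5 ms after the step end) skips the initial
    elastic recoil.
    """
    if protocol.delta_T > 0:
        raise EstimationError("Vsh is defined for negative (shortening) steps")
    if protocol.delta_T == 0:
        return 0.0
    t_a = protocol.t_end + window[0]
    t_b = protocol.t_end + window[1]
    slope, _ = _line_over_window(transient.time, transient.x, t_a, t_b)
    return slope


def estimate_step_response(
    transient: Transient, protocol: ForceStepProtocol
) -> StepEstimates:
    """Populate the estimates appropriate to the record's state and step sign."""
    est = StepEstimates(
        delta_T=protocol.delta_T, SL0=transient.SL0, state=transient.state
    )
    est.windows["Vi"] = (protocol.t_end, protocol.t_end + VI_WINDOW)
    if transient.state == "OFF":
        est.Vi = estimate_Vi(transient, protocol)
        if protocol.delta_T >= 0:
            est.L2, _ = estimate_L2(transient, protocol)
    else:
        if protocol.delta_T >= 0:
            est.L1 = estimate_L1(transient, protocol)
            est.L2, est.V3 = estimate_L2(transient, protocol)
        else:
            est.Vsh = estimate_Vsh(transient, protocol)
    return est


def _pooled_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if len(x) < 2:
        raise EstimationError("need at least 2 points for a linear fit")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate abscissa: all x equal")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    i_se, s_se = res.bse if len(x) > 2 else (np.nan, np.nan)
    cov = res.cov_params() if len(x) > 2 else np.full((2, 2), np.nan)
    if slope != 0:
        x0 = -intercept / slope
        # delta method on (-b0/b1) with the full fit covariance
        grad = np.array([-1.0 / slope, intercept / slope**2])
        x0_var = float(grad @ cov @ grad)
        x0_se = float(np.sqrt(x0_var)) if np.isfinite(x0_var) and x0_var >= 0 else np.nan
    else:
        x0, x0_se = np.nan, np.nan
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(s_se),
        intercept_se=float(i_se),
        r2=float(res.rsquared) if len(x) > 2 else 1.0,
        n_points=len(x),
        abscissa_intercept=x0,
        abscissa_intercept_se=x0_se,
        mode="pooled",
    )


def fit_relation(
    points: Sequence[tuple[float, float]] | Mapping[str, Sequence[tuple[float, float]]],
    mode: str = "pooled",
) -> LinearFit:
    """Fit a straight line to (step size, estimate) points.

    ``mode='pooled'`` fits one OLS line through all points.
    ``mode='per_fiber_average'`` expects a mapping fiber -> points, fits each
    fiber separately and averages the per-fiber slopes and intercepts (the
    standard errors are then those of the averages).  The slope is
    interpreted by the caller as ``1/eta`` (velocity relations) or ``1/e``
    (amplitude relations).
    """
    if mode == "pooled":
        if isinstance(points, Mapping):
            pts = [p for fiber_pts in points.values() for p in fiber_pts]
        else:
            pts = list(points)
        arr = np.asarray(pts, dtype=float)
        return _pooled_fit(arr[:, 0], arr[:, 1])
    if mode != "per_fiber_average":
        raise EstimationError(f"unknown fit mode {mode!r}")
    if not isinstance(points, Mapping):
        raise EstimationError("per_fiber_average requires a mapping fiber -> points")
    if len(points) < 2:
        raise EstimationError("per_fiber_average requires >= 2 fibers")
    fits = []
    for fiber, fiber_pts in points.items():
        arr = np.asarray(list(fiber_pts), dtype=float)
        if len(arr) < 2:
            raise EstimationError(f"fiber {fiber!r} has fewer than 2 points")
        fits.append(_pooled_fit(arr[:, 0], arr[:, 1]))
    slopes = np.array([f.slope for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    n = len(fits)
    slope, intercept = float(slopes.mean()), float(intercepts.mean())
    s_se = float(slopes.std(ddof=1) / np.sqrt(n))
    i_se = float(intercepts.std(ddof=1) / np.sqrt(n))
    if slope != 0:
        x0 = -intercept / slope
        x0_se = float(
            np.sqrt((i_se / slope) ** 2 + (intercept * s_se / slope**2) ** 2)
        )
    else:
        x0, x0_se = np.nan, np.nan
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=s_se,
        intercept_se=i_se,
        r2=float(np.mean([f.r2 for f in fits])),
        n_points=int(sum(f.n_points for f in fits)),
        abscissa_intercept=x0,
        abscissa_intercept_se=x0_se,
        mode="per_fiber_average",
    )


def fit_fluidity_vs_SL(fluidities: Sequence[tuple[float, float]]) -> LinearFit:
    """Linear fit of resting fluidity ``1/eta_i`` against sarcomere length.

    The abscissa intercept estimates the SL at which the tandem Ig segment
    reaches its contour length and the resting fluidity vanishes.
    """
    arr = np.asarray(list(fluidities), dtype=float)
    if len(np.unique(arr[:, 0])) < 2:
        raise EstimationError("need fluidities at >= 2 distinct sarcomere lengths")
    return _pooled_fit(arr[:, 0], arr[:, 1])


def compare_groups(
    a: Iterable[float], b: Iterable[float], alpha: float = 0.02
) -> tuple[float, bool]:
    """Welch two-tailed t-test between two groups of estimates.

    Returns ``(p_value, significant)`` with significance declared at
    ``p < alpha`` (default 0.02).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EstimationError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0, False
        raise EstimationError("zero variance in both groups: t-test degenerate")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), bool(p < alpha)
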