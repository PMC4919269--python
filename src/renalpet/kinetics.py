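"""One-tissue compartment fitting and Logan graphical analysis.

The one-tissue compartment model (1TCM) describes tracer exchange between
blood and a single tissue compartment with an influx rate constant K1
(mL blood per mL tissue per minute, written 1/min) and a backflux rate
constant k2 (1/min):

    C_T(t) = K1 * (C_p (*) e^{-k2 t})(t)

Fitting minimises the unweighted residual sum of squares over all frames
with bounded nonlinear least squares; fits with non-physiological
estimates are flagged rather than silently kept.  The Logan plot turns
late-time reversible kinetics into a straight line whose slope is the
total distribution volume V_T (= K1/k2 for the 1TCM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, interpolate, optimize, signal

from .clearance import auc
from .cohort import FrameSchedule, TimeActivityCurve, ValidationError

__all__ = [
    "OneTissueFit",
    "LoganResult",
    "forward_1tcm",
    "fit_1tcm",
    "is_physiological",
    "logan_vt",
    "K1_BOUNDS",
    "K2_BOUNDS",
]

#: physiological plausibility windows for the flag below (1/min)
K1_BOUNDS = (1e-4, 10.0)
K2_BOUNDS = (0.0, 5.0)
#: relative standard error of K1 above which a fit counts as unidentifiable
MAX_REL_SE_K1 = 2.0


@dataclass(frozen=True)
class OneTissueFit:
    K1: float
    k2: float
    rss: float
    se_K1: float
    se_k2: float
    converged: bool
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class LoganResult:
    slope: float  # V_T, mL/mL
    intercept: float  # min
    t_star: float  # min
    r_squared: float
    n_points: int


# --------------------------------------------------------------------------
# forward model from a sampled input TAC
# --------------------------------------------------------------------------

def _reconstruct_input(input_tac: TimeActivityCurve, grid: np.ndarray) -> np.ndarray:
    """Continuous input curve on ``grid`` from frame-averaged samples.

    The running integral of the input is known exactly at frame edges
    (frame mean x duration, summed); a monotone cubic (PCHIP) through
    those points is differentiated to give a smooth, non-negative curve
    whose frame means reproduce the measured TAC exactly.  This recovers
    sharp bolus shapes far better than interpolating the frame means at
    midpoints.
    """
    sched = input_tac.schedule
    a_min = sched.frame_start_s / 60.0
    b_min = sched.frame_end_s / 60.0
    edges = np.concatenate([a_min, [b_min[-1]]])
    cum = np.concatenate([[0.0], np.cumsum(input_tac.values * (b_min - a_min))])
    if edges[0] > 0:  # integral is zero before the first frame
        edges = np.concatenate([[0.0], edges])
        cum = np.concatenate([[0.0], cum])
    pchip = interpolate.PchipInterpolator(edges, cum)
    cp = pchip.derivative()(np.clip(grid, edges[0], edges[-1]))
    return np.maximum(cp, 0.0)


def _fine_grid_prediction(
    cp: np.ndarray,
    grid: np.ndarray,
    K1: float,
    k2: float,
) -> np.ndarray:
    """Frame-free tissue curve: exact convolution update per linear segment.

    The fine-grid input ``cp`` is treated as piecewise linear; the
    convolution with K1*e^{-k2 t} is advanced with the exact update for a
    linear segment, so the only discretisation error is the sampling of
    the input itself.
    """
    dt = grid[1] - grid[0]
    a = cp[:-1]
    b = cp[1:]
    if k2 > 0:
        alpha = np.exp(-k2 * dt)
        m = (b - a) / dt
        seg = b * (1.0 - alpha) / k2 - m * (1.0 - (1.0 + k2 * dt) * alpha) / (k2 * k2)
    else:
        alpha = 1.0
        seg = 0.5 * (a + b) * dt
    # C[n+1] = alpha * C[n] + K1 * seg[n]  — a first-order IIR recursion
    x = np.concatenate([[0.0], K1 * seg])
    return signal.lfilter([1.0], [1.0, -alpha], x)


def forward_1tcm(
    input_tac: TimeActivityCurve,
    K1: float,
    k2: float,
    schedule: FrameSchedule | None = None,
    fine_dt_s: float = 0.25,
) -> TimeActivityCurve:
    """Frame-averaged 1TCM prediction driven by a sampled input TAC."""
    if K1 < 0 or k2 < 0:
        raise ValidationError("K1 and k2 must be >= 0")
    sched = schedule or input_tac.schedule
    end_min = max(sched.frame_end_s[-1], input_tac.schedule.frame_end_s[-1]) / 60.0
    n_steps = max(int(np.ceil(end_min / (fine_dt_s / 60.0))), 2)
    grid = np.linspace(0.0, end_min, n_steps + 1)
    cp = _reconstruct_input(input_tac, grid)
    ct = _fine_grid_prediction(cp, grid, K1, k2)
    cum = np.concatenate([[0.0], integrate.cumulative_trapezoid(ct, grid)])
    a_min = sched.frame_start_s / 60.0
    b_min = sched.frame_end_s / 60.0
    means = (np.interp(b_min, grid, cum) - np.interp(a_min, grid, cum)) / (b_min - a_min)
    return TimeActivityCurve(sched, means, region_label="1tcm_prediction")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def is_physiological(fit: OneTissueFit) -> tuple[bool, str]:
    """Plausibility gate for a 1TCM fit.

    The windows are reporting policy, not biology: they catch rate
    constants pinned at bounds, runaway estimates, and fits whose K1 is
    statistically unidentifiable (relative SE > 2).
    """
    if not fit.converged:
        return False, "did not converge"
    # interior-point optimizers stop fractionally inside the box, so a
    # parameter within relative 1e-6 of a bound counts as pinned
    tol = 1e-6
    if not (K1_BOUNDS[0] * (1 + tol) < fit.K1 < K1_BOUNDS[1] * (1 - tol)):
        return False, "K1 out of range"
    if not (K2_BOUNDS[0] < fit.k2 < K2_BOUNDS[1] * (1 - tol)):
        return False, "k2 out of range"
    if not np.isfinite(fit.se_K1) or fit.se_K1 / fit.K1 > MAX_REL_SE_K1:
        return False, "unidentifiable"
    return True, ""


def fit_1tcm(
    cortex_tac: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    init: tuple[float, float] = (0.1, 0.1),
    bounds: tuple[tuple[float, float], tuple[float, float]] = (K1_BOUNDS, K2_BOUNDS),
    fine_dt_s: float = 0.25,
    duration_weighted: bool = False,
    max_iterations: int = 500,
) -> OneTissueFit:
    """Least-squares 1TCM fit of a tissue TAC against a sampled input.

    Unweighted residual sum of squares over all frames by default
    (``duration_weighted=True`` scales residuals by sqrt(frame duration)).
    Bounded trust-region least squares; asymptotic standard errors come
    from the Jacobian at the optimum.  Non-convergence and degenerate data
    are reported through the flags, never raised.
    """
    sched = cortex_tac.schedule
    if sched.count != input_tac.schedule.count or not np.allclose(
        sched.frame_start_s, input_tac.schedule.frame_start_s
    ):
        raise ValidationError("cortex and input TACs must share one schedule")
    data = cortex_tac.values
    w = np.sqrt(sched.frame_duration_s / 60.0) if duration_weighted else np.ones(sched.count)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pred = forward_1tcm(input_tac, theta[0], theta[1], sched, fine_dt_s)
        return w * (pred.values - data)

    lo = (bounds[0][0], bounds[1][0])
    hi = (bounds[0][1], bounds[1][1])
    x0 = np.clip(np.asarray(init, dtype=float), lo, hi)
    try:
        res = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=3 * max_iterations,
        )
    except Exception as exc:  # defensive: optimizer failure is a flagged fit
        fit = OneTissueFit(float("nan"), float("nan"), float("nan"), float("nan"),
                           float("nan"), converged=False)
        return replace(fit, excluded=True, exclusion_reason=f"optimizer error: {exc}")
    K1, k2 = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))
    converged = bool(res.status > 0)
    dof = sched.count - 2
    se = (float("nan"), float("nan"))
    if converged and dof > 0:
        jtj = res.jac.T @ res.jac
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov = (rss / dof) * np.linalg.pinv(jtj)
                diag = np.clip(np.diag(cov), 0.0, None)
                se = (float(np.sqrt(diag[0])), float(np.sqrt(diag[1])))
            except np.linalg.LinAlgError:
                pass
    fit = OneTissueFit(K1, k2, rss, se[0], se[1], converged)
    ok, reason = is_physiological(fit)
    if not ok:
        fit = replace(fit, excluded=True, exclusion_reason=reason)
    return fit


# --------------------------------------------------------------------------
# Logan graphical analysis
# --------------------------------------------------------------------------

def logan_vt(
    tissue_tac: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    t_star: float = 20.0,
) -> LoganResult:
    """Logan plot slope (total distribution volume) from ``t_star`` on.

    Regresses ``int_0^t C_T / C_T(t)`` on ``int_0^t C_p / C_T(t)`` over
    frames whose midpoint is at or beyond ``t_star`` minutes; running
    integrals use the frame-rectangle rule.  For reversible kinetics the
    late-time slope estimates V_T = K1/k2.
    """
    sched = tissue_tac.schedule
    if sched.count != input_tac.schedule.count or not np.allclose(
        sched.frame_start_s, input_tac.schedule.frame_start_s
    ):
        raise ValidationError("tissue and input TACs must share one schedule")
    mid = sched.mid_min
    sel = mid >= t_star
    if int(np.sum(sel)) < 3:
        raise ValidationError("need at least 3 frames with midpoint >= t_star")
    if np.any(tissue_tac.values[sel] <= 0):
        raise ValidationError("tissue TAC must be positive beyond t_star")
    idx = np.nonzero(sel)[0]
    int_ct = np.array([auc(tissue_tac, 0.0, float(mid[i])) for i in idx])
    int_cp = np.array([auc(input_tac, 0.0, float(mid[i])) for i in idx])
    ct = tissue_tac.values[idx]
    x = int_cp / ct
    y = int_ct / ct
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LoganResult(float(slope), float(intercept), float(t_star), min(r2, 1.0), int(idx.size))
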