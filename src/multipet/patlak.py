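"""Modified reference-tissue Patlak graphical analysis for irreversible tracers.

The reference region (cerebellar gray matter for the MAO-B tracer) itself
accumulates tracer irreversibly, so its measured curve is first corrected for
trapping at a fixed rate k3_ref (default 0.01 min⁻¹) to recover the free
reference curve C_f. The graphical transform then plots

    y(t) = C_T(t) / C_f(t)    against    x(t) = ∫₀ᵗ C_f(τ) dτ / C_f(t)

and an ordinary least-squares line over a late fit window (default 20–60 min)
yields the slope kI — the net tracer binding rate — and the intercept, the
initial tracer distribution volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .tac import TimeActivityCurve

__all__ = [
    "PatlakResult",
    "PatlakPoints",
    "ReferencePatlak",
    "correct_reference_tac",
    "patlak_transform",
    "fit_patlak",
    "ded_slope_pipeline",
]


@dataclass(frozen=True)
class PatlakResult:
    """Outcome of the windowed Patlak line fit."""

    slope: float  # kI, min⁻¹ — net tracer binding
    intercept: float  # initial distribution volume, unitless
    residual_sd: float
    fit_window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class PatlakPoints:
    """Graphical-transform coordinates with their frame midpoints (minutes)."""

    midpoints_min: np.ndarray
    x: np.ndarray  # normalised integrated reference, minutes
    y: np.ndarray  # tissue-to-reference ratio, unitless


def _cumulative_frame_integral(t_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Trapezoidal cumulative integral over frame midpoints, accumulated from
    injection: the first segment [0, t_0] uses the first frame value (so a
    constant curve integrates to c·t exactly)."""
    out = np.empty_like(values, dtype=float)
    out[0] = t_min[0] * values[0]
    dt = np.diff(t_min)
    out[1:] = np.cumsum((values[:-1] + values[1:]) / 2.0 * dt)
    out[1:] += out[0]
    return out


def correct_reference_tac(ref: TimeActivityCurve, k3_ref: float) -> TimeActivityCurve:
    """Remove irreversible trapping from a measured reference curve.

    Solves C_ref(t) = C_f(t) + k3_ref·∫₀ᵗ C_f(τ)dτ for the free curve C_f by
    forward recursion over frames (trapezoidal cumulative integral, first
    segment from injection). With k3_ref = 0 the input is returned unchanged;
    the output never exceeds the input.
    """
    if k3_ref < 0:
        raise ValueError("k3_ref must be >= 0")
    t = ref.midpoints_min
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame midpoints must be strictly increasing")
    if k3_ref == 0:
        return TimeActivityCurve(ref.schedule, ref.values.copy())
    cref = ref.values
    cf = np.empty_like(cref)
    # first segment: C_ref0 = C_f0 + k3_ref·t0·C_f0
    cf[0] = cref[0] / (1.0 + k3_ref * t[0])
    integral = t[0] * cf[0]
    for i in range(1, len(cref)):
        dt = t[i] - t[i - 1]
        # C_ref_i = C_f_i + k3_ref·(I_{i-1} + (C_f_{i-1}+C_f_i)/2·dt)
        cf[i] = (cref[i] - k3_ref * (integral + cf[i - 1] * dt / 2.0)) / (
            1.0 + k3_ref * dt / 2.0
        )
        integral += (cf[i - 1] + cf[i]) / 2.0 * dt
    return TimeActivityCurve(ref.schedule, np.maximum(cf, 0.0))


def patlak_transform(target: TimeActivityCurve, ref_corrected: TimeActivityCurve) -> PatlakPoints:
    """Graphical Patlak coordinates from target and (corrected) reference TACs."""
    if target.schedule != ref_corrected.schedule:
        raise ValueError("target and reference must share the same frame schedule")
    cf = ref_corrected.values
    bad = np.flatnonzero(cf <= 0)
    if bad.size:
        raise ValueError(f"reference activity is zero/negative at frame {bad[0]}")
    t = target.midpoints_min
    integral = _cumulative_frame_integral(t, cf)
    return PatlakPoints(midpoints_min=t, x=integral / cf, y=target.values / cf)


def fit_patlak(points: PatlakPoints, window: tuple[float, float] = (20.0, 60.0)) -> PatlakResult:
    """OLS line through the transform points whose frame midpoints fall inside
    the (inclusive) window. Unweighted, deterministic."""
    lo, hi = window
    sel = (points.midpoints_min >= lo) & (points.midpoints_min <= hi)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"only {n} frame midpoints inside window {window}; need >= 3")
    x = points.x[sel]
    y = points.y[sel]
    if np.ptp(x) <= 0 or np.var(x) == 0:
        raise ValueError("degenerate x variance in fit window")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return PatlakResult(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        fit_window=(float(lo), float(hi)),
        n_points=n,
    )


class ReferencePatlak(BaseEstimator):
    """Reference-tissue Patlak estimator (scikit-learn style).

    Parameters
    ----------
    k3_ref : float, default 0.01
        Fixed irreversible-trapping rate (min⁻¹) removed from the reference
        curve before the transform.
    window : tuple of float, default (20, 60)
        Fit window in minutes; frames with midpoints inside the inclusive
        bounds enter the line fit.

    Attributes (after ``fit``)
    --------------------------
    slope_ : float
        kI, the net tracer binding rate (min⁻¹).
    intercept_ : float
        Initial tracer distribution volume.
    residual_sd_ : float
    n_points_ : int
    points_ : PatlakPoints
        The full transform, for plotting/diagnostics.
    """

    def __init__(self, k3_ref: float = 0.01, window: tuple[float, float] = (20.0, 60.0)):
        self.k3_ref = k3_ref
        self.window = window

    def fit(self, target: TimeActivityCurve, ref: TimeActivityCurve) -> "ReferencePatlak":
        ref_free = correct_reference_tac(ref, self.k3_ref)
        self.points_ = patlak_transform(target, ref_free)
        result = fit_patlak(self.points_, tuple(self.window))
        self.slope_ = result.slope
        self.intercept_ = result.intercept
        self.residual_sd_ = result.residual_sd
        self.n_points_ = result.n_points
        self.result_ = result
        return self

    def predict(self, x) -> np.ndarray:
        """Fitted line evaluated at normalised-time coordinates ``x``."""
        if not hasattr(self, "slope_"):
            raise AttributeError("ReferencePatlak instance is not fitted yet")
        return self.slope_ * np.asarray(x, dtype=float) + self.intercept_


def ded_slope_pipeline(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    k3_ref: float = 0.01,
    window: tuple[float, float] = (20.0, 60.0),
) -> PatlakResult:
    """Per-region quantifier: correct the reference, transform, fit the line."""
    return ReferencePatlak(k3_ref=k3_ref, window=window).fit(target, ref).result_
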