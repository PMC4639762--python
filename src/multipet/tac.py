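"""Forward kinetic models and frame sampling for dynamic PET.

Generates continuous tissue time-activity curves from an irreversible
two-tissue compartment model driven by a synthetic bolus input, averages them
over an acquisition frame schedule, and applies a duration-weighted
multiplicative noise model. All curves are decay-corrected by convention.

Units follow PET practice: time in minutes inside the kinetic model (rate
constants are per-minute), frame definitions in seconds, activity
concentration in kBq/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "KineticParams",
    "TimeActivityCurve",
    "InputFunction",
    "default_grid_min",
    "plasma_input",
    "tissue_tac",
    "sample_frames",
    "add_noise",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames given as (start_s, duration_s)."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("schedule must contain at least one frame")
        start0 = self.frames[0][0]
        if start0 != 0.0:
            raise ValueError(f"first frame must start at 0 s, got {start0}")
        prev_end = 0.0
        for i, (start, dur) in enumerate(self.frames):
            if dur <= 0.0:
                raise ValueError(f"frame {i} has non-positive duration {dur}")
            if start != prev_end:
                raise ValueError(
                    f"frame {i} starts at {start} s but previous frame ends at {prev_end} s"
                )
            prev_end = start + dur

    @classmethod
    def from_durations(cls, durations_s) -> "FrameSchedule":
        starts = np.concatenate([[0.0], np.cumsum(durations_s)[:-1]])
        return cls(tuple((float(s), float(d)) for s, d in zip(starts, durations_s)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames])

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes; the representative time of each frame."""
        return (self.starts_s + self.durations_s / 2.0) / 60.0

    @property
    def total_duration_min(self) -> float:
        return float(self.ends_s[-1] / 60.0)


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue irreversible compartment rates.

    K1 (ml·cm⁻³·min⁻¹) delivers tracer from plasma, k2 (min⁻¹) clears the free
    compartment back to plasma, and k3 (min⁻¹) traps irreversibly. For a
    reference region k3 plays the role of the small residual trapping rate.
    """

    K1: float
    k2: float
    k3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/ml) on a schedule."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {vals.shape} does not match {self.schedule.n_frames} frames"
            )
        if np.any(vals < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.schedule.midpoints_min


@dataclass(frozen=True)
class InputFunction:
    """Synthetic bolus plasma input: linear rise to a peak, then a
    multi-exponential decay. Fractions weight the decay terms and must sum
    to 1 so the curve is continuous at the peak."""

    peak_time_min: float = 1.0
    peak_kbq_ml: float = 30.0
    fractions: tuple[float, ...] = (0.70, 0.20, 0.10)
    decay_rates_per_min: tuple[float, ...] = (2.5, 0.25, 0.02)

    def __post_init__(self) -> None:
        if self.peak_time_min <= 0 or self.peak_kbq_ml < 0:
            raise ValueError("peak time must be > 0 and peak amplitude >= 0")
        if len(self.fractions) != len(self.decay_rates_per_min):
            raise ValueError("fractions and decay rates must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("decay fractions must sum to 1")
        if any(r <= 0 for r in self.decay_rates_per_min):
            raise ValueError("decay rates must be > 0")


def default_grid_min(step_s: float = 1.0, span_s: float = 3600.0) -> np.ndarray:
    """Fine simulation grid in minutes (default 1 s steps over 60 min)."""
    return np.arange(0.0, span_s + step_s / 2, step_s) / 60.0


def plasma_input(t_min, params: InputFunction = InputFunction()) -> np.ndarray:
    """Evaluate the plasma input (kBq/ml) at times ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("plasma input is undefined for negative times")
    rise = params.peak_kbq_ml * t / params.peak_time_min
    tail = np.zeros_like(t)
    dt = np.maximum(t - params.peak_time_min, 0.0)
    for frac, rate in zip(params.fractions, params.decay_rates_per_min):
        tail += params.peak_kbq_ml * frac * np.exp(-rate * dt)
    out = np.where(t <= params.peak_time_min, rise, tail)
    return out if out.shape else float(out)


def _c1_response(cp: np.ndarray, t_min: np.ndarray, K1: float, a: float) -> np.ndarray:
    """Free-compartment curve K1·Cp ⊗ exp(−a t) on a uniform grid.

    Uses the exact one-step exponential-decay update with trapezoidal
    treatment of Cp inside each step, realised as an IIR filter.
    """
    dt = np.diff(t_min)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")
    if dt.size == 0:
        return np.zeros_like(cp)
    h = float(dt[0])
    e = np.exp(-a * h)
    # C1[i] = e·C1[i−1] + K1·h/2·(e·Cp[i−1] + Cp[i])
    b = [K1 * h / 2.0, K1 * h / 2.0 * e]
    out = lfilter(b, [1.0, -e], cp)
    out[0] = 0.0
    return out


def tissue_tac(params: KineticParams, input_fn: InputFunction, t_grid_min: np.ndarray) -> np.ndarray:
    """Total tissue curve C1+C2 of the irreversible 2TCM on a fine grid.

    Solves dC1/dt = K1·Cp − (k2+k3)·C1 and dC2/dt = k3·C1; with k3 = 0 this
    reduces to the reversible one-tissue model.
    """
    t = np.asarray(t_grid_min, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("grid must be strictly increasing from 0")
    cp = plasma_input(t, input_fn)
    c1 = _c1_response(cp, t, params.K1, params.k2 + params.k3)
    if params.k3 == 0.0:
        return c1
    c2 = params.k3 * cumulative_trapezoid(c1, t, initial=0.0)
    return c1 + c2


def tissue_tac_multi(
    K1: float, k2: float, k3_values: np.ndarray, input_fn: InputFunction, t_grid_min: np.ndarray
) -> np.ndarray:
    """Vectorised 2TCM forward model over several k3 values (rows of output)."""
    t = np.asarray(t_grid_min, dtype=float)
    cp = plasma_input(t, input_fn)
    out = np.empty((len(k3_values), t.size))
    for i, k3 in enumerate(np.asarray(k3_values, dtype=float)):
        c1 = _c1_response(cp, t, K1, k2 + k3)
        out[i] = c1 if k3 == 0 else c1 + k3 * cumulative_trapezoid(c1, t, initial=0.0)
    return out


def sample_frames(t_grid_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average a continuous curve over each acquisition frame.

    value_i = (1/Δ_i)·∫ curve over frame i, by trapezoidal quadrature on the
    fine grid (exact for linear integrands). Supports 2-D ``curve`` with one
    row per region, in which case an array of shape (rows, frames) is
    returned instead of a TimeActivityCurve.
    """
    t = np.asarray(t_grid_min, dtype=float)
    c = np.asarray(curve, dtype=float)
    if t[-1] * 60.0 + 1e-6 < schedule.ends_s[-1]:
        raise ValueError(
            f"schedule extends to {schedule.ends_s[-1]} s beyond curve support {t[-1] * 60.0} s"
        )
    cum = cumulative_trapezoid(c, t, initial=0.0, axis=-1)
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    if c.ndim == 1:
        frame_int = np.interp(ends, t, cum) - np.interp(starts, t, cum)
        values = frame_int / (schedule.durations_s / 60.0)
        return TimeActivityCurve(schedule, np.maximum(values, 0.0))
    frame_int = np.stack([np.interp(ends, t, row) - np.interp(starts, t, row) for row in cum])
    return np.maximum(frame_int / (schedule.durations_s / 60.0), 0.0)


def add_noise(tac: TimeActivityCurve, cv: float, seed) -> TimeActivityCurve:
    """Multiplicative Gaussian noise scaled by frame duration.

    Per-frame standard deviation is cv·value/√(Δ_i/Δ_max), so longer frames
    (more counts) are less noisy; negative results are clipped to zero.
    ``seed`` may be an int, SeedSequence or Generator.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return TimeActivityCurve(tac.schedule, tac.values.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    durations = tac.schedule.durations_s
    sd = cv * tac.values / np.sqrt(durations / durations.max())
    noisy = tac.values + rng.normal(size=tac.values.shape) * sd
    return TimeActivityCurve(tac.schedule, np.clip(noisy, 0.0, None))
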