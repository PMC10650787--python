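"""Forward (simulation) side of the one- and two-tissue compartment models.

The measured PET signal for a tissue region driven by a whole-blood input
C_b(t) (here the left-ventricle curve; no metabolite correction) is

    C_model(t) = (1 - vp) * (h (*) C_b)(t) + vp * C_b(t)

where h is the tissue impulse response. For the two-tissue model,

    h(t) = A1 exp(-alpha1 t) + A2 exp(-alpha2 t)
    alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2
    A1 = K1 (k3+k4-alpha1)/(alpha2-alpha1),  A2 = K1 (alpha2-k3-k4)/(alpha2-alpha1)

and for the one-tissue model h(t) = K1 exp(-k2 t). The input is represented
as a piecewise-linear interpolant anchored at the frame midpoints and pinned
to zero at t=0 (an IP injection starts at zero activity). Convolution with
each exponential term is evaluated *exactly* per linear segment on a uniform
grid via a first-order linear recurrence, and frame values are the exact
time-averages of the continuous model over each frame (PET frames integrate
counts; this matters for the 10-s frames of fast-kinetics protocols).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .exceptions import ExtrapolationError
from .tac import FrameSchedule, TimeActivityCurve

_ALPHA_FLOOR = 1e-12  # avoids a separate alpha=0 branch; error O(alpha*T) ~ 1e-10
_REPEATED_ROOT_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams2TC:
    """Two-tissue compartment rate constants (1/min) and blood volume fraction."""

    K1: float
    k2: float
    k3: float
    k4: float
    vp: float = 0.0

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4", "vp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError("vp must lie in [0, 1]")

    @property
    def bp_nd(self) -> float:
        """Non-displaceable binding potential k3/k4; defined only for k4 > 0."""
        if self.k4 <= 0:
            raise ValueError("BP_ND undefined for k4 = 0")
        return self.k3 / self.k4

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.vp])


@dataclass(frozen=True)
class KineticParams1TC:
    """One-tissue compartment rate constants (1/min) and blood volume fraction."""

    K1: float
    k2: float
    vp: float = 0.0

    def __post_init__(self):
        for name in ("K1", "k2", "vp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError("vp must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.vp])


@dataclass(frozen=True)
class BiexponentialIR:
    """Impulse response h(t) = A1 e^(-alpha1 t) + A2 e^(-alpha2 t).

    When the eigenvalues coincide (``repeated`` is True) the response is the
    analytic limit h(t) = (A1+A2) e^(-alpha t) + t_amplitude * t e^(-alpha t)
    with alpha = alpha1 = alpha2; A1, A2 are then stored as (K1, 0).
    """

    alpha1: float
    alpha2: float
    A1: float
    A2: float
    repeated: bool = False
    t_amplitude: float = 0.0


def impulse_response_2tc(params: KineticParams2TC) -> BiexponentialIR:
    """Eigen-decomposition of the two-tissue model into exponential modes."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    if s <= 0:
        raise ValueError("k2 + k3 + k4 must be positive")
    disc = s * s - 4.0 * k2 * k4
    root = math.sqrt(max(disc, 0.0))
    if root <= _REPEATED_ROOT_RTOL * s:
        alpha = 0.5 * s
        return BiexponentialIR(
            alpha1=alpha, alpha2=alpha, A1=K1, A2=0.0,
            repeated=True, t_amplitude=K1 * (k3 + k4 - alpha),
        )
    alpha1 = 0.5 * (s - root)
    alpha2 = 0.5 * (s + root)
    A1 = K1 * (k3 + k4 - alpha1) / (alpha2 - alpha1)
    A2 = K1 * (alpha2 - k3 - k4) / (alpha2 - alpha1)
    return BiexponentialIR(alpha1=alpha1, alpha2=alpha2, A1=A1, A2=A2)


# ---------------------------------------------------------------------------
# Piecewise-linear input representation


@dataclass(frozen=True)
class SampledInput:
    """Uniform fine-grid view of the piecewise-linear input interpolant.

    Anchored at frame midpoints, pinned to 0 at t=0, constant beyond the
    last midpoint. ``cumulative`` is the exact running integral at the grid
    nodes (trapezoid is exact for a piecewise-linear function).
    """

    times: np.ndarray
    values: np.ndarray
    step: float
    support_end: float  # end of the last frame of the source TAC

    @property
    def cumulative(self) -> np.ndarray:
        try:
            return self._cum  # type: ignore[attr-defined]
        except AttributeError:
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * self.step * (self.values[1:] + self.values[:-1]))]
            )
            object.__setattr__(self, "_cum", cum)
            return cum

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


def default_grid_step(schedule: FrameSchedule) -> float:
    """Grid step dividing the shortest frame: <= 0.25 min (or 0.05 for sub-minute frames)."""
    d = float(np.min(schedule.durations))
    cap = 0.25 if d >= 1.0 else 0.05
    return d / math.ceil(d / cap)


def interpolate_input(
    blood: TimeActivityCurve,
    grid_step: float | None = None,
    t_end: float | None = None,
) -> SampledInput:
    """Piecewise-linear interpolant of the blood curve on a uniform grid.

    Knots are the frame midpoints plus (0, 0); evaluation beyond the last
    midpoint is constant. The grid spans [0, t_end] (default: end of the
    blood scan) rounded up to a whole number of steps.
    """
    if blood.schedule.n_frames < 2:
        raise ValueError("input interpolation requires >= 2 frames")
    if grid_step is None:
        grid_step = default_grid_step(blood.schedule)
    end = blood.schedule.total_duration if t_end is None else float(t_end)
    n = int(math.ceil(end / grid_step - 1e-9))
    times = np.arange(n + 1) * grid_step
    knot_t = np.concatenate([[0.0], blood.schedule.midpoints])
    knot_v = np.concatenate([[0.0], blood.values])
    values = np.interp(times, knot_t, knot_v)
    return SampledInput(times=times, values=values, step=grid_step,
                        support_end=blood.schedule.total_duration)


# ---------------------------------------------------------------------------
# Exact exponential convolution of a piecewise-linear input


def _exp_conv_with_cumulative(u: np.ndarray, dt: float, alpha: float):
    """y(t) = int_0^t e^{-alpha (t-s)} u(s) ds at the grid nodes, plus its
    exact running integral Y(t) = (U(t) - y(t)) / alpha (from y' = u - alpha y)."""
    alpha = max(alpha, _ALPHA_FLOOR)
    x = alpha * dt
    d = math.exp(-x)
    E1 = -math.expm1(-x) / alpha
    if x < 1e-6:
        G = dt * dt * (0.5 - x / 6.0 + x * x / 24.0)
    else:
        G = (dt - E1) / alpha
    c_prev = E1 - G / dt
    c_next = G / dt
    drive = np.empty_like(u)
    drive[0] = 0.0
    drive[1:] = c_prev * u[:-1] + c_next * u[1:]
    y = lfilter([1.0], [1.0, -d], drive)
    U = np.concatenate([[0.0], np.cumsum(0.5 * dt * (u[1:] + u[:-1]))])
    Y = (U - y) / alpha
    return y, Y


def _texp_conv_with_cumulative(u: np.ndarray, dt: float, alpha: float):
    """z(t) = int_0^t (t-s) e^{-alpha (t-s)} u(s) ds and its running integral
    Z = (Y - z)/alpha (from z' = y - alpha z); used for the repeated-root limit."""
    alpha = max(alpha, _ALPHA_FLOOR)
    x = alpha * dt
    d = math.exp(-x)
    y, Y = _exp_conv_with_cumulative(u, dt, alpha)
    # segment integrals: H1 = int_0^dt s e^{-alpha s} ds,
    # H3 = int_0^dt s^2 e^{-alpha s} ds  (exact, with small-x series)
    if x < 1e-4:
        H1 = dt * dt * (0.5 - x / 3.0 + x * x / 8.0)
        H3 = dt ** 3 * (1.0 / 3.0 - x / 4.0 + x * x / 10.0)
    else:
        H1 = (1.0 - d * (1.0 + x)) / (alpha * alpha)
        H3 = (2.0 - d * (x * x + 2.0 * x + 2.0)) / (alpha ** 3)
    H2 = (dt * H1 - H3) / dt  # int (dt-s) s/dt e^{-alpha(dt-s)} ds, reflected
    drive = np.empty_like(u)
    drive[0] = 0.0
    drive[1:] = (H1 - H2) * u[:-1] + H2 * u[1:]
    # z_{n+1} = d z_n + dt d y_n + segment term
    drive[1:] += dt * d * y[:-1]
    z = lfilter([1.0], [1.0, -d], drive)
    Z = (Y - z) / alpha
    return z, Z


class TissueSimulator:
    """Reusable forward model for one (blood curve, output schedule) pair.

    Precomputes the input grid and per-frame boundary indices so repeated
    parameter evaluations during fitting cost only the exponential
    recurrences. Frame values are exact time-averages of the continuous
    model when frame boundaries fall on grid nodes (true for the standard
    schedules); otherwise the cumulative integral is interpolated linearly
    between nodes (second-order accurate).
    """

    def __init__(
        self,
        blood: TimeActivityCurve,
        schedule: FrameSchedule,
        grid_step: float | None = None,
    ):
        if grid_step is None:
            grid_step = min(default_grid_step(schedule), default_grid_step(blood.schedule))
        if schedule.total_duration > blood.schedule.total_duration + 1e-9:
            raise ExtrapolationError(
                f"schedule extends to {schedule.total_duration} min but blood TAC "
                f"ends at {blood.schedule.total_duration} min"
            )
        self.schedule = schedule
        self.blood = blood
        self.input = interpolate_input(blood, grid_step, t_end=schedule.total_duration)
        self._u = self.input.values
        self._dt = self.input.step
        self._grid_t = self.input.times
        self._U = self.input.cumulative
        bounds = np.concatenate([schedule.starts, schedule.ends])
        self._bounds = bounds
        self._durations = schedule.durations
        # frame-averaged blood values (for the vp term)
        self._blood_frame_avg = self._frame_avg_from_cumulative(self._U)

    def _frame_avg_from_cumulative(self, cum: np.ndarray) -> np.ndarray:
        vals = np.interp(self._bounds, self._grid_t, cum)
        n = self.schedule.n_frames
        return (vals[n:] - vals[:n]) / self._durations

    def frame_values(self, params: KineticParams2TC | KineticParams1TC) -> np.ndarray:
        """Per-frame time-averages of C_model for the given parameters."""
        if isinstance(params, KineticParams1TC):
            _, Y = _exp_conv_with_cumulative(self._u, self._dt, params.k2)
            conv_cum = params.K1 * Y
        else:
            ir = impulse_response_2tc(params)
            _, Y1 = _exp_conv_with_cumulative(self._u, self._dt, ir.alpha1)
            if ir.repeated:
                _, Z = _texp_conv_with_cumulative(self._u, self._dt, ir.alpha1)
                conv_cum = (ir.A1 + ir.A2) * Y1 + ir.t_amplitude * Z
            else:
                _, Y2 = _exp_conv_with_cumulative(self._u, self._dt, ir.alpha2)
                conv_cum = ir.A1 * Y1 + ir.A2 * Y2
        tissue_avg = self._frame_avg_from_cumulative(conv_cum)
        return (1.0 - params.vp) * tissue_avg + params.vp * self._blood_frame_avg


def simulate_tissue_tac(
    params: KineticParams2TC | KineticParams1TC,
    blood: TimeActivityCurve,
    schedule: FrameSchedule,
    grid_step: float | None = None,
    region: str = "",
) -> TimeActivityCurve:
    """Simulate a noise-free tissue TAC on ``schedule`` driven by ``blood``."""
    sim = TissueSimulator(blood, schedule, grid_step)
    return TimeActivityCurve(
        schedule=schedule,
        values=sim.frame_values(params),
        unit=blood.unit,
        subject=blood.subject,
        region=region,
        ligand=blood.ligand,
        group=blood.group,
    )
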