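"""Reference-tissue quantification: SRTM and Logan graphical analysis.

The simplified reference tissue model (SRTM) describes a target-region TAC
in terms of a reference-region TAC with no (or negligible) specific binding:

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) * (C_R (*) e^(-k2a t)),  k2a = k2/(1+BP)

with R1 the relative delivery (K1/K1'), k2 the target efflux rate and BP the
binding potential. The reference efflux constant k2' = k2/R1 feeds the
reference-tissue Logan plot

    Y(T) = int_0^T C_T dt / C_T(T)
    X(T) = (int_0^T C_R dt + C_R(T)/k2') / C_T(T)

whose late-time slope (T >= t*) estimates the distribution volume ratio DVR.
Under ideal reference assumptions DVR = BP_ND + 1; a reference region with
residual specific binding biases the DVR downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, InsufficientDataError
from .fitting import FitOptions
from .models import SampledInput, _exp_conv_with_cumulative, default_grid_step, interpolate_input
from .tac import TimeActivityCurve

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS_SRTM: dict[str, tuple[float, float]] = {
    "R1": (0.01, 10.0),
    "k2": (1e-4, 5.0),
    "BP": (-0.95, 30.0),
}


@dataclass(frozen=True)
class SrtmParams:
    """SRTM parameters; k2_ref is the derived reference efflux k2' = k2/R1."""

    R1: float
    k2: float
    BP: float

    def __post_init__(self):
        if self.R1 <= 0:
            raise ValueError("R1 must be > 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.BP <= -1:
            raise ValueError("BP must be > -1")

    @property
    def k2_ref(self) -> float:
        return self.k2 / self.R1

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BP)


@dataclass(frozen=True)
class LoganResult:
    """Reference-tissue Logan regression: slope (DVR), intercept, segment info."""

    dvr: float
    intercept: float
    t_star: float
    n_points_used: int
    r_squared: float


@dataclass(frozen=True)
class DvrBpPair:
    """BP_ND + 1 from the compartment fit paired with the Logan DVR."""

    bp_plus_one: float
    dvr: float


def dvr_from_bp(bp_nd: float) -> float:
    """DVR equivalent of a binding potential: DVR = BP_ND + 1."""
    if not np.isfinite(bp_nd):
        raise ValueError("bp_nd must be finite")
    return bp_nd + 1.0


class SrtmSimulator:
    """Forward SRTM model against a fixed reference TAC (reusable across starts).

    The direct delivery term uses the measured reference frame values, so a
    target identical to the reference is reproduced exactly by R1=1, BP=0;
    the interpolated reference enters only through the convolution term
    (frame-averaged via its exact cumulative integral).
    """

    def __init__(self, reference: TimeActivityCurve, grid_step: float | None = None):
        if np.all(reference.values == 0):
            raise ValueError("reference TAC must not be identically zero")
        self.schedule = reference.schedule
        step = grid_step if grid_step is not None else default_grid_step(self.schedule)
        self.input: SampledInput = interpolate_input(reference, step)
        self._u = self.input.values
        self._dt = self.input.step
        self._grid_t = self.input.times
        self._ref_values = reference.values
        self._bounds = np.concatenate([self.schedule.starts, self.schedule.ends])
        self._durations = self.schedule.durations

    def frame_values(self, params: SrtmParams) -> np.ndarray:
        k2a = max(params.k2a, 1e-12)
        _, Y = _exp_conv_with_cumulative(self._u, self._dt, k2a)
        coeff = params.k2 - params.R1 * k2a
        n = self.schedule.n_frames
        at_bounds = np.interp(self._bounds, self._grid_t, coeff * Y)
        conv_avg = (at_bounds[n:] - at_bounds[:n]) / self._durations
        return params.R1 * self._ref_values + conv_avg


def simulate_srtm_tac(
    params: SrtmParams, reference: TimeActivityCurve, region: str = ""
) -> TimeActivityCurve:
    """Noise-free target TAC from the SRTM forward model (used for testing/synthesis)."""
    sim = SrtmSimulator(reference)
    return TimeActivityCurve(
        schedule=reference.schedule, values=sim.frame_values(params),
        unit=reference.unit, subject=reference.subject, region=region,
        ligand=reference.ligand, group=reference.group,
    )


def fit_srtm(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    options: FitOptions | None = None,
) -> SrtmParams:
    """Bounded multi-start least-squares SRTM fit; returns (R1, k2, BP).

    Shares the multi-start semantics of the compartment-model fitting:
    uniform random starts in the bounds box, deterministic given the seed.
    """
    options = options or FitOptions()
    if target.schedule != reference.schedule:
        raise ValueError("target and reference must share one frame schedule")
    sim = SrtmSimulator(reference, options.grid_step)
    bounds = DEFAULT_BOUNDS_SRTM
    names = list(bounds)
    lo = np.array([bounds[p][0] for p in names])
    hi = np.array([bounds[p][1] for p in names])
    obs = target.values
    w = np.sqrt(
        target.schedule.durations if options.weighting == "frame-duration"
        else np.ones(target.schedule.n_frames)
    )

    def residuals(x):
        return w * (sim.frame_values(SrtmParams(*x)) - obs)

    rng = np.random.default_rng(options.seed)
    starts = rng.uniform(lo, hi, size=(options.n_starts, 3))
    # R1=1, modest k2, BP=1 is a sensible deterministic anchor start
    starts[0] = np.clip([1.0, 0.1, 1.0], lo, hi)

    best, diagnostics = None, []
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=options.max_nfev)
        except Exception as exc:
            diagnostics.append({"start": i, "error": str(exc)})
            continue
        wss = float(np.dot(sol.fun, sol.fun))
        diagnostics.append({"start": i, "wss": wss, "status": sol.status})
        if best is None or wss < best[1]:
            best = (sol.x, wss)
    if best is None:
        raise FitError("all SRTM starts failed", diagnostics)
    return SrtmParams(*best[0])


def _logan_coordinates(
    target: TimeActivityCurve, reference: TimeActivityCurve, k2_ref: float
):
    """Logan X/Y coordinates at the frame midpoints (trapezoid integrals with
    a zero anchor at t=0, consistent with the input interpolation)."""
    t = target.schedule.midpoints
    ct = target.values
    cr = reference.values
    t0 = np.concatenate([[0.0], t])
    int_t = np.cumsum(0.5 * np.diff(t0) * (np.concatenate([[0.0], ct])[:-1] + ct))
    int_r = np.cumsum(0.5 * np.diff(t0) * (np.concatenate([[0.0], cr])[:-1] + cr))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = int_t / ct
        x = (int_r + cr / k2_ref) / ct
    return t, x, y


def _auto_t_star(t, x, y, max_rel_dev: float = 0.10, min_points: int = 4) -> int:
    """Smallest start index whose segment deviates from its own regression
    line by at most ``max_rel_dev`` (relative to |y|), keeping >= min_points.
    Falls back to the latest admissible segment if none qualifies."""
    n = len(t)
    last_i = n - min_points
    for i in range(last_i + 1):
        xi, yi = x[i:], y[i:]
        slope, intercept = np.polyfit(xi, yi, 1)
        resid = yi - (slope * xi + intercept)
        rel = np.abs(resid) / np.maximum(np.abs(yi), 1e-300)
        if np.max(rel) <= max_rel_dev:
            return i
    logger.warning("no Logan start time met the %.0f%% linearity rule; "
                   "using the final %d points", 100 * max_rel_dev, min_points)
    return last_i


def logan_reference_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2_ref: float,
    t_star: float | None = None,
) -> LoganResult:
    """Reference-tissue Logan analysis; the late-segment slope is the DVR.

    ``t_star=None`` selects the start time automatically (max 10% relative
    deviation from the segment's own regression line, >= 4 points).
    """
    if k2_ref <= 0:
        raise ValueError("k2_ref must be positive")
    if target.schedule != reference.schedule:
        raise ValueError("target and reference must share one frame schedule")
    t, x, y = _logan_coordinates(target, reference, k2_ref)
    ok = np.isfinite(x) & np.isfinite(y)
    t, x, y = t[ok], x[ok], y[ok]
    if t_star is None:
        if len(t) < 4:
            raise InsufficientDataError("Logan auto-t* needs >= 4 usable midpoints")
        i0 = _auto_t_star(t, x, y)
    else:
        i0 = int(np.searchsorted(t, t_star - 1e-9))
    if len(t) - i0 < 3:
        raise InsufficientDataError(
            f"fewer than 3 Logan points at/after t*={t_star} min"
        )
    xi, yi = x[i0:], y[i0:]
    slope, intercept = np.polyfit(xi, yi, 1)
    yhat = slope * xi + intercept
    ss_res = float(np.sum((yi - yhat) ** 2))
    ss_tot = float(np.sum((yi - np.mean(yi)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LoganResult(
        dvr=float(slope), intercept=float(intercept), t_star=float(t[i0]),
        n_points_used=int(len(xi)), r_squared=float(min(r2, 1.0)),
    )
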