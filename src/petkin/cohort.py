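"""Synthetic cohorts: IP-injection-shaped blood input functions and
group-specific tissue TACs, so the whole pipeline runs without animal data.

The left-ventricle input is modeled as a Bateman (double-exponential)
function, C_b(t) = A (e^(-lam_e t) - e^(-lam_a t)) — the simplest shape with
a delayed peak and a slow tail, appropriate for intraperitoneal injection.
Its amplitude and elimination rate are calibrated so the frame-averaged
curve reproduces the published peak SUV (at a chosen time-to-peak) and the
mean SUV over the final 30 min of the scan.

Tissue TACs are generated by the package's own two-tissue forward model
driven by the frame-sampled blood curve, with per-subject rate constants
drawn from truncated normals around the published group means. Fitting the
noise-free curves therefore recovers each subject's constants exactly
(up to optimizer tolerance), which is the intended baseline for the
noise-injection study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import CalibrationError
from .models import KineticParams2TC, TissueSimulator
from .reported_values import (
    DEFAULT_T_PEAK_MIN,
    FRAME_SCHEDULE_SPECS,
    LATE_WINDOW_MIN,
    LV_SUV_SUMMARY,
    RATE_CONSTANTS,
)
from .tac import SUV, FrameSchedule, SubjectMeta, TimeActivityCurve, make_frame_schedule

LV_REGION = "left_ventricle"


@dataclass(frozen=True)
class BatemanInput:
    """Calibrated continuous input C_b(t) = A (e^(-lam_e t) - e^(-lam_a t))."""

    amplitude: float
    lambda_absorption: float  # 1/min, fast
    lambda_elimination: float  # 1/min, slow

    def __post_init__(self):
        if not (self.lambda_absorption > self.lambda_elimination > 0):
            raise ValueError("need lambda_absorption > lambda_elimination > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * (
            np.exp(-self.lambda_elimination * t) - np.exp(-self.lambda_absorption * t)
        )

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        """Exact per-frame time-averages of the continuous curve."""
        def primitive(t):
            return self.amplitude * (
                -np.exp(-self.lambda_elimination * t) / self.lambda_elimination
                + np.exp(-self.lambda_absorption * t) / self.lambda_absorption
            )
        a, b = schedule.starts, schedule.ends
        return (primitive(b) - primitive(a)) / (b - a)


@dataclass(frozen=True)
class InputFunctionSpec:
    """Targets for the blood curve: peak SUV at t_peak and late-window mean."""

    peak_suv: float
    late_mean_suv: float
    t_peak_min: float
    late_window_min: float = LATE_WINDOW_MIN
    scan_end_min: float | None = None  # default: taken from the schedule

    def __post_init__(self):
        if min(self.peak_suv, self.late_mean_suv, self.t_peak_min) <= 0:
            raise ValueError("peak, late mean and t_peak must be positive")
        if self.late_mean_suv >= self.peak_suv:
            raise CalibrationError("late mean must be below the peak")


def _lambda_a_for_peak(lam_e: float, t_peak: float) -> float:
    """Solve t_peak = ln(lam_a/lam_e)/(lam_a - lam_e) for lam_a > lam_e."""

    def g(lam_a):
        return math.log(lam_a / lam_e) / (lam_a - lam_e) - t_peak

    lo = lam_e * (1 + 1e-9)
    hi = lam_e * 2.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            raise CalibrationError("could not bracket the absorption rate")
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-14)


def calibrate_input(spec: InputFunctionSpec, scan_end_min: float) -> BatemanInput:
    """Fit (A, lam_a, lam_e) to the (peak, t_peak, late-mean) targets.

    Closed-form amplitude plus one scalar root-solve in lam_e (each trial
    lam_e fixes lam_a through the time-to-peak condition).
    """
    t1 = scan_end_min - spec.late_window_min
    t2 = scan_end_min
    if t1 <= spec.t_peak_min:
        raise CalibrationError("late window must start after the peak")

    def late_mean(lam_e):
        lam_a = _lambda_a_for_peak(lam_e, spec.t_peak_min)
        amp = spec.peak_suv / (
            math.exp(-lam_e * spec.t_peak_min) - math.exp(-lam_a * spec.t_peak_min)
        )
        integral = amp * (
            (math.exp(-lam_e * t1) - math.exp(-lam_e * t2)) / lam_e
            - (math.exp(-lam_a * t1) - math.exp(-lam_a * t2)) / lam_a
        )
        return integral / (t2 - t1)

    lo, hi = 1e-6, (1.0 - 1e-6) / spec.t_peak_min
    f = lambda lam_e: late_mean(lam_e) - spec.late_mean_suv
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"peak {spec.peak_suv} at {spec.t_peak_min} min and late mean "
            f"{spec.late_mean_suv} over [{t1}, {t2}] min are infeasible for a "
            "Bateman input"
        )
    lam_e = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    lam_a = _lambda_a_for_peak(lam_e, spec.t_peak_min)
    amp = spec.peak_suv / (
        math.exp(-lam_e * spec.t_peak_min) - math.exp(-lam_a * spec.t_peak_min)
    )
    return BatemanInput(amplitude=amp, lambda_absorption=lam_a, lambda_elimination=lam_e)


def make_input_function(
    spec: InputFunctionSpec,
    schedule: FrameSchedule,
    subject: str = "",
    ligand: str = "",
    group: str = "",
) -> TimeActivityCurve:
    """Frame-averaged calibrated Bateman input as a left-ventricle TAC (SUV)."""
    end = spec.scan_end_min or schedule.total_duration
    if spec.t_peak_min >= end:
        raise CalibrationError("schedule must cover the peak time")
    bateman = calibrate_input(spec, end)
    return TimeActivityCurve(
        schedule=schedule, values=bateman.frame_averages(schedule), unit=SUV,
        subject=subject, region=LV_REGION, ligand=ligand, group=group,
    )


def default_input_spec(ligand: str) -> InputFunctionSpec:
    """Published WT peak / late-mean SUV targets for the given ligand."""
    summary = LV_SUV_SUMMARY[ligand]
    return InputFunctionSpec(
        peak_suv=summary["peak"]["WT"][0],
        late_mean_suv=summary["late_mean"]["WT"][0],
        t_peak_min=DEFAULT_T_PEAK_MIN[ligand],
    )


@dataclass(frozen=True)
class CohortSpec:
    """One synthetic group: ligand, group label, size and dispersion scale."""

    ligand: str
    group: str
    n_subjects: int
    seed: int = 0
    regions: tuple[str, ...] = ("thalamus", "midbrain", "cerebellum")
    dispersion_scale: float = 1.0  # multiplies the published between-subject SDs
    vp_mean: float = 0.05
    vp_sd: float = 0.01

    def __post_init__(self):
        if self.ligand not in RATE_CONSTANTS:
            raise ValueError(f"unknown ligand {self.ligand!r}")
        if self.group not in RATE_CONSTANTS[self.ligand]:
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        missing = set(self.regions) - set(RATE_CONSTANTS[self.ligand][self.group])
        if missing:
            raise ValueError(f"no published rate constants for regions {sorted(missing)}")


@dataclass
class SyntheticSubject:
    subject_id: str
    meta: SubjectMeta
    blood: TimeActivityCurve  # kBq/cc
    regions: dict[str, TimeActivityCurve]  # kBq/cc
    truth: dict[str, KineticParams2TC]
    input_scale: float


@dataclass
class Cohort:
    spec: CohortSpec
    schedule: FrameSchedule
    subjects: list[SyntheticSubject]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for region, p in s.truth.items():
                rows.append({
                    "subject": s.subject_id, "ligand": self.spec.ligand,
                    "group": self.spec.group, "region": region,
                    "K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                    "vp": p.vp, "bp_nd": p.bp_nd,
                })
        return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lower, upper=np.inf):
    """Rejection-sampled truncated normal (cheap at these acceptance rates)."""
    if sd <= 0:
        return mean
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed to accept")


def generate_cohort(
    spec: CohortSpec,
    schedule: FrameSchedule | None = None,
    input_spec: InputFunctionSpec | None = None,
) -> Cohort:
    """Generate a synthetic cohort; byte-identical on rerun with a fixed seed.

    Rate constants are drawn per subject from truncated normals (published
    mean and SD, truncated below at 10% of the mean); each subject shares a
    single input function across regions, scaled by a per-subject amplitude
    factor with the published peak-SUV relative SD. TACs are stored in
    kBq/cc with the subject's injected dose and body weight, so reading
    them back exercises SUV conversion.
    """
    if schedule is None:
        schedule = make_frame_schedule(FRAME_SCHEDULE_SPECS[spec.ligand])
    input_spec = input_spec or default_input_spec(spec.ligand)
    rng = np.random.default_rng(spec.seed)
    table = RATE_CONSTANTS[spec.ligand][spec.group]
    peak_mean, peak_sd = LV_SUV_SUMMARY[spec.ligand]["peak"]["WT"]
    rel_sd = peak_sd / peak_mean

    base_blood_suv = make_input_function(
        input_spec, schedule, ligand=spec.ligand, group=spec.group
    )

    subjects = []
    for i in range(spec.n_subjects):
        sid = f"{spec.ligand}-{spec.group}-{i:02d}"
        weight = _truncated_normal(rng, 25.0, 3.0, 15.0, 40.0)
        dose = _truncated_normal(rng, 7.4, 1.5, 2.0, 15.0)
        meta = SubjectMeta(injected_dose_mbq=dose, body_weight_g=weight)
        scale = _truncated_normal(rng, 1.0, rel_sd, 0.2, 3.0)
        suv_to_kbq = dose * 1000.0 / weight

        blood_suv = base_blood_suv.with_values(base_blood_suv.values * scale)
        truth = {}
        for region in spec.regions:
            draws = {}
            for k, (mean, sd) in table[region].items():
                draws[k] = _truncated_normal(
                    rng, mean, sd * spec.dispersion_scale, 0.1 * mean
                )
            draws["vp"] = _truncated_normal(rng, spec.vp_mean, spec.vp_sd, 0.005, 0.3)
            truth[region] = KineticParams2TC(**draws)

        sim = TissueSimulator(blood_suv, schedule)
        regions = {}
        for region in spec.regions:
            suv_values = sim.frame_values(truth[region])
            regions[region] = TimeActivityCurve(
                schedule=schedule, values=suv_values * suv_to_kbq, unit="kBq/cc",
                subject=sid, region=region, ligand=spec.ligand, group=spec.group,
            )
        blood_kbq = TimeActivityCurve(
            schedule=schedule, values=blood_suv.values * suv_to_kbq, unit="kBq/cc",
            subject=sid, region=LV_REGION, ligand=spec.ligand, group=spec.group,
        )
        subjects.append(SyntheticSubject(
            subject_id=sid, meta=meta, blood=blood_kbq, regions=regions,
            truth=truth, input_scale=scale,
        ))
    return Cohort(spec=spec, schedule=schedule, subjects=subjects)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write TAC files plus a manifest CSV; returns the manifest path."""
    from .tac import write_tac_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        for region, tac in [(LV_REGION, s.blood)] + sorted(s.regions.items()):
            fname = f"{s.subject_id}_{region}.csv"
            write_tac_table(tac, out / fname)
            rows.append({
                "subject": s.subject_id, "region": region, "path": fname,
                "ligand": cohort.spec.ligand, "group": cohort.spec.group,
                "injected_dose_mbq": s.meta.injected_dose_mbq,
                "body_weight_g": s.meta.body_weight_g,
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.truth_frame().to_csv(out / "truth.csv", index=False)
    return manifest
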