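"""Frame schedules, time-activity curves, SUV conversion and TAC file I/O.

All times are minutes internally; rate constants elsewhere in the package
are 1/min. Readers convert seconds on ingest where a spec is given in
seconds. Activity concentrations are either ``kBq/cc`` or dimensionless
``SUV`` (tissue density 1 g/cc assumed, the small-animal convention).
Decay correction is assumed to have been applied upstream during
reconstruction; this module neither applies nor removes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ScheduleError, TacParseError, UnitError

logger = logging.getLogger(__name__)

KBQ_CC = "kBq/cc"
SUV = "SUV"
_UNITS = (KBQ_CC, SUV)


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start/end times in minutes, contiguous or not, non-overlapping."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.size < 1 or starts.shape != ends.shape:
            raise ScheduleError("starts/ends must be equal-length 1-d arrays with >= 1 frame")
        if np.any(ends <= starts):
            raise ScheduleError("every frame must have end > start")
        if np.any(np.diff(starts) < 0):
            raise ScheduleError("frame starts must be non-decreasing")
        if np.any(starts[1:] < ends[:-1] - 1e-12):
            raise ScheduleError("frames must not overlap")
        if np.any(np.diff(self.midpoints) <= 0):
            raise ScheduleError("frame midpoints must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_duration(self) -> float:
        """End of the last frame, in minutes."""
        return float(self.ends[-1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and self.starts.shape == other.starts.shape
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __len__(self) -> int:
        return self.n_frames


def make_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule starting at t=0 from (count, duration_seconds) blocks.

    ``[(10, 60), (17, 600)]`` gives the 27-frame, 180-min 2-FA schedule;
    ``[(12, 10), (18, 60), (8, 300)]`` the 38-frame, 60-min Nifene schedule.
    """
    if not spec:
        raise ScheduleError("empty schedule spec")
    durations_min = []
    for count, dur_s in spec:
        if count < 1:
            raise ScheduleError(f"block count must be >= 1, got {count}")
        if dur_s <= 0:
            raise ScheduleError(f"frame duration must be positive, got {dur_s}")
        durations_min.extend([dur_s / 60.0] * int(count))
    ends = np.cumsum(durations_min)
    starts = ends - np.asarray(durations_min)
    return FrameSchedule(starts=starts, ends=ends)


@dataclass(frozen=True)
class SubjectMeta:
    """Injected dose (MBq) and body weight (g) for SUV normalization."""

    injected_dose_mbq: float
    body_weight_g: float

    def __post_init__(self):
        if not (self.injected_dose_mbq > 0):
            raise ValueError("injected dose must be strictly positive")
        if not (self.body_weight_g > 0):
            raise ValueError("body weight must be strictly positive")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-aligned activity concentrations with unit tag and identity metadata."""

    schedule: FrameSchedule
    values: np.ndarray
    unit: str = KBQ_CC
    subject: str = ""
    region: str = ""
    ligand: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValueError(
                f"values length {values.size} does not match frame count {self.schedule.n_frames}"
            )
        if self.unit not in _UNITS:
            raise UnitError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    @property
    def times(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return self.schedule.midpoints

    def with_values(self, values, unit: str | None = None) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TimeActivityCurve)
            and self.schedule == other.schedule
            and np.array_equal(self.values, other.values)
            and (self.unit, self.subject, self.region, self.ligand, self.group)
            == (other.unit, other.subject, other.region, other.ligand, other.group)
        )


def to_suv(tac: TimeActivityCurve, meta: SubjectMeta) -> TimeActivityCurve:
    """Convert a kBq/cc TAC to SUV: value / (injected dose [kBq] / body weight [g]).

    1 g of tissue is taken as 1 cc, so the SUV is dimensionless.
    """
    if tac.unit == SUV:
        raise UnitError("TAC is already in SUV")
    dose_kbq = meta.injected_dose_mbq * 1000.0
    factor = dose_kbq / meta.body_weight_g
    return tac.with_values(tac.values / factor, unit=SUV)


def from_suv(tac: TimeActivityCurve, meta: SubjectMeta) -> TimeActivityCurve:
    """Inverse of :func:`to_suv` (exact to machine precision up to rounding)."""
    if tac.unit != SUV:
        raise UnitError("TAC is not in SUV")
    dose_kbq = meta.injected_dose_mbq * 1000.0
    factor = dose_kbq / meta.body_weight_g
    return tac.with_values(tac.values * factor, unit=KBQ_CC)


def late_window_summary(tac: TimeActivityCurve, window_min: float) -> tuple[float, float]:
    """(peak, late mean): max over all frames, and unweighted mean of frames whose
    start time is at or after (scan end - window)."""
    end = tac.schedule.total_duration
    if window_min >= end:
        raise ValueError("late window must be shorter than the scan duration")
    cutoff = end - window_min
    mask = tac.schedule.starts >= cutoff - 1e-9
    if not np.any(mask):
        raise ValueError("late window covers no complete frame")
    return float(np.max(tac.values)), float(np.mean(tac.values[mask]))


# ---------------------------------------------------------------------------
# TAC table I/O: delimited text with commented metadata header.
#
#   # subject: m01
#   # region: thalamus
#   # ligand: 2-FA
#   # group: WT
#   # unit: kBq/cc
#   frame_start_min,frame_end_min,value
#   0.0,1.0,12.5
#   ...

_REQUIRED_COLS = ("frame_start_min", "frame_end_min", "value")
_META_KEYS = ("subject", "region", "ligand", "group", "unit")


def write_tac_table(tac: TimeActivityCurve, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}: {getattr(tac, key)}\n")
        fh.write(delimiter.join(_REQUIRED_COLS) + "\n")
        for s, e, v in zip(tac.schedule.starts, tac.schedule.ends, tac.values):
            fh.write(f"{float(s)!r}{delimiter}{float(e)!r}{delimiter}{float(v)!r}\n")


def read_tac_table(path, delimiter: str | None = None) -> TimeActivityCurve:
    """Read a TAC table; comma default with tab auto-detect; extra columns ignored."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if delimiter is None:
                delimiter = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delimiter)]
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None or not rows:
        raise TacParseError(f"{path}: no data rows found")
    missing = [c for c in _REQUIRED_COLS if c not in header]
    if missing:
        raise TacParseError(f"{path}: missing required column(s) {missing}")
    extras = [c for c in header if c not in _REQUIRED_COLS]
    if extras:
        logger.warning("%s: ignoring unknown column(s) %s", path, extras)
    idx = {c: header.index(c) for c in _REQUIRED_COLS}

    starts, ends, values = [], [], []
    for rownum, (lineno, fields) in enumerate(rows):
        try:
            s = float(fields[idx["frame_start_min"]])
            e = float(fields[idx["frame_end_min"]])
            v = float(fields[idx["value"]])
        except (ValueError, IndexError) as exc:
            raise TacParseError(f"{path}: unparsable row: {exc}", row=rownum) from exc
        if not np.isfinite(v):
            raise TacParseError(f"{path}: non-finite value", row=rownum)
        if e <= s:
            raise TacParseError(f"{path}: frame end {e} <= start {s}", row=rownum)
        starts.append(s)
        ends.append(e)
        values.append(v)
    try:
        schedule = FrameSchedule(starts=np.array(starts), ends=np.array(ends))
    except ScheduleError as exc:
        raise TacParseError(f"{path}: invalid schedule: {exc}") from exc
    return TimeActivityCurve(
        schedule=schedule,
        values=np.array(values),
        unit=meta.get("unit", KBQ_CC),
        subject=meta.get("subject", ""),
        region=meta.get("region", ""),
        ligand=meta.get("ligand", ""),
        group=meta.get("group", ""),
    )
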