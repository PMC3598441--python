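"""Domain types and exposure-covariate derivation.

Exposure histories are piecewise-linear intensity profiles over age
(fibers/ml for occupational asbestos, but any protracted exposure fits).
From a profile the four classic temporal aspects of exposure are derived
at any age ``t``:

* ``duration``   — years exposed up to ``t``,
* ``intensity``  — cumulated intensity up to ``t`` divided by duration
  (the mean index of exposure, MIE),
* ``age_first_exposure`` — constant in ``t``,
* ``time_since_last_exposure`` — years since cessation.

Follow-up data travel in the standard counting-process long format:
one row per (start, stop] interval with interval-constant covariates
and an event indicator on the terminal interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PATTERN_CLASSES = (
    "constant",
    "highly_increasing",
    "moderately_increasing",
    "moderately_decreasing",
)

#: covariate names entering each regression model
MODEL_COVARIATES = {
    1: ("intensity", "duration"),
    2: ("intensity", "duration", "age_first_exposure"),
    3: ("intensity", "duration", "time_since_last_exposure"),
}


class DataError(ValueError):
    """Structurally invalid input data."""


# ---------------------------------------------------------------------------
# exposure trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureTrajectory:
    """A subject's piecewise-linear exposure-intensity profile over age.

    ``profile_ages``/``profile_values`` are the nodes of the profile on
    ``[age_first_exposure, age_last_exposure]``; intensity is linearly
    interpolated between nodes and zero outside the exposed window.
    """

    subject_id: object
    age_first_exposure: float
    age_last_exposure: float
    profile_ages: np.ndarray
    profile_values: np.ndarray
    pattern_class: str = "constant"

    def __post_init__(self):
        ages = np.asarray(self.profile_ages, dtype=float)
        vals = np.asarray(self.profile_values, dtype=float)
        object.__setattr__(self, "profile_ages", ages)
        object.__setattr__(self, "profile_values", vals)
        if not self.age_first_exposure < self.age_last_exposure:
            raise DataError(
                f"subject {self.subject_id}: age_first_exposure must be "
                "strictly below age_last_exposure"
            )
        if ages.ndim != 1 or ages.shape != vals.shape or ages.size < 2:
            raise DataError("profile needs >=2 (age, value) nodes")
        if np.any(np.diff(ages) <= 0):
            raise DataError("profile ages must be strictly increasing")
        if not np.isclose(ages[0], self.age_first_exposure) or not np.isclose(
            ages[-1], self.age_last_exposure
        ):
            raise DataError("profile nodes must span the exposure window")
        if np.any(vals < 0):
            raise DataError("intensity profile must be non-negative")
        if self.pattern_class not in PATTERN_CLASSES:
            raise DataError(f"unknown pattern class {self.pattern_class!r}")

    @classmethod
    def from_linear(
        cls,
        subject_id,
        age_first: float,
        age_last: float,
        intercept: float,
        slope: float,
        pattern_class: str = "constant",
    ) -> "ExposureTrajectory":
        """Build from a clamped-linear profile max(0, intercept + slope*(a - age_first)).

        A zero crossing inside the window becomes an explicit node so the
        stored profile stays piecewise linear and exact.
        """
        w = age_last - age_first
        ages = [age_first, age_last]
        vals = [max(0.0, intercept), max(0.0, intercept + slope * w)]
        if slope != 0.0 and intercept > 0.0:
            x0 = -intercept / slope
            if 0.0 < x0 < w:
                ages = [age_first, age_first + x0, age_last]
                v_end = max(0.0, intercept + slope * w)
                vals = [intercept, 0.0, v_end]
        return cls(subject_id, age_first, age_last, np.array(ages), np.array(vals),
                   pattern_class)

    def intensity_at(self, age: float) -> float:
        """Instantaneous intensity (0 outside the exposure window)."""
        if age < self.age_first_exposure or age > self.age_last_exposure:
            return 0.0
        return float(np.interp(age, self.profile_ages, self.profile_values))

    def cumulated_intensity(self, t: float) -> float:
        """Exact integral of the profile from age_first_exposure to min(t, age_last)."""
        u = min(t, self.age_last_exposure)
        if u <= self.age_first_exposure:
            return 0.0
        ages = self.profile_ages
        vals = self.profile_values
        k = int(np.searchsorted(ages, u, side="right"))
        xs = np.concatenate([ages[:k], [u]])
        ys = np.concatenate([vals[:k], [np.interp(u, ages, vals)]])
        return float(np.trapezoid(ys, xs))


def exposure_covariates_at(
    trajectory: ExposureTrajectory, t: float, model: int = 1
) -> dict[str, float]:
    """Time-dependent exposure covariates of a trajectory at age ``t``.

    duration(t) = clamp(min(t, age_last) - age_first, 0); intensity(t) is the
    cumulated intensity divided by duration (0 before first exposure, frozen
    after cessation since neither numerator nor denominator changes);
    time_since_last_exposure(t) = max(0, t - age_last).
    """
    if model not in MODEL_COVARIATES:
        raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}")
    a0, a1 = trajectory.age_first_exposure, trajectory.age_last_exposure
    duration = max(0.0, min(t, a1) - a0)
    intensity = trajectory.cumulated_intensity(t) / duration if duration > 0 else 0.0
    full = {
        "intensity": intensity,
        "duration": duration,
        "age_first_exposure": a0,
        "time_since_last_exposure": max(0.0, t - a1),
    }
    return {name: full[name] for name in MODEL_COVARIATES[model]}


# ---------------------------------------------------------------------------
# counting-process records and IO
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountingProcessRecord:
    """One (start, stop] follow-up interval with interval-constant covariates."""

    subject_id: object
    start: float
    stop: float
    event: int
    covariates: Mapping[str, float]

    def __post_init__(self):
        if not self.start < self.stop:
            raise DataError(
                f"subject {self.subject_id}: interval start must be < stop"
            )
        if self.event not in (0, 1):
            raise DataError(f"subject {self.subject_id}: event flag must be 0/1")


def _validate_subject_records(sid, recs: list[CountingProcessRecord]) -> None:
    recs.sort(key=lambda r: r.start)
    n_events = sum(r.event for r in recs)
    if n_events > 1:
        raise DataError(f"subject {sid}: more than one event record")
    for a, b in zip(recs, recs[1:]):
        if b.start < a.stop - 1e-12:
            raise DataError(
                f"subject {sid}: overlapping intervals "
                f"({a.start},{a.stop}] and ({b.start},{b.stop}]"
            )
        if b.start > a.stop + 1e-12:
            raise DataError(
                f"subject {sid}: gap between ({a.start},{a.stop}] "
                f"and ({b.start},{b.stop}]"
            )
    if n_events == 1 and recs[-1].event != 1:
        raise DataError(f"subject {sid}: event must be on the terminal interval")


def read_counting_process(path) -> list[CountingProcessRecord]:
    """Read a counting-process CSV (id,start,stop,event,covariate...).

    Records come back grouped by subject and sorted by interval start, with
    the structural invariants (no overlap, no gaps, one event per subject,
    event on the last interval) enforced.
    """
    df = pd.read_csv(path)
    required = {"id", "start", "stop", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"missing required columns: {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    for col in ("start", "stop", "event", *cov_cols):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise DataError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    out: list[CountingProcessRecord] = []
    for sid, g in df.groupby("id", sort=True):
        recs = [
            CountingProcessRecord(
                sid,
                float(r.start),
                float(r.stop),
                int(r.event),
                {c: float(getattr(r, c)) for c in cov_cols},
            )
            for r in g.itertuples()
        ]
        _validate_subject_records(sid, recs)
        out.extend(recs)
    return out


def write_counting_process(records: Iterable[CountingProcessRecord], path) -> None:
    """Write records to CSV; ``read_counting_process`` inverts this exactly."""
    records = list(records)
    cov_cols: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    rows = [
        {
            "id": r.subject_id,
            "start": r.start,
            "stop": r.stop,
            "event": r.event,
            **{c: r.covariates.get(c, np.nan) for c in cov_cols},
        }
        for r in sorted(records, key=lambda r: (str(r.subject_id), r.start))
    ]
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", *cov_cols])
    df.to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Sequence[CountingProcessRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record collection."""
    cov_cols: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    return pd.DataFrame(
        [
            {"id": r.subject_id, "start": r.start, "stop": r.stop, "event": r.event,
             **{c: r.covariates.get(c, np.nan) for c in cov_cols}}
            for r in records
        ],
        columns=["id", "start", "stop", "event", *cov_cols],
    )


# ---------------------------------------------------------------------------
# case-control studies
# ---------------------------------------------------------------------------


@dataclass
class CaseControlStudy:
    """Sampled cases and controls with index ages and matched-set structure.

    ``data`` columns: sampled_unit_id (unique per row), source_subject_id,
    status ('case'/'control'), index_age, set_id.  ``trajectories`` maps a
    source subject id to its :class:`ExposureTrajectory` (may be shared by
    several sampled rows: controls are drawn with replacement).
    """

    data: pd.DataFrame
    trajectories: Mapping[object, ExposureTrajectory] = field(default_factory=dict)

    REQUIRED = ("sampled_unit_id", "source_subject_id", "status", "index_age", "set_id")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise DataError(f"case-control table missing columns {sorted(missing)}")
        if self.data["sampled_unit_id"].duplicated().any():
            raise DataError("sampled_unit_id values must be unique")
        bad = ~self.data["status"].isin(["case", "control"])
        if bad.any():
            raise DataError("status must be 'case' or 'control'")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == "control").sum())

    def validate_ratio(self, m: int) -> None:
        counts = (
            self.data[self.data["status"] == "control"].groupby("set_id").size()
        )
        sets = self.data[self.data["status"] == "case"]["set_id"]
        if not counts.reindex(sets).eq(m).all():
            raise DataError(f"every matched set must contain exactly {m} controls")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, trajectories=None) -> "CaseControlStudy":
        return cls(pd.read_csv(path), trajectories or {})


# ---------------------------------------------------------------------------
# job histories and the mean index of exposure (MIE)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JobRecord:
    """One job's exposure assessment from a job-exposure matrix.

    ``probability`` is the chance the job was exposed at all; the specific-task
    and ambient (frequency, intensity) pairs describe how much when it was.
    """

    start_age: float
    duration: float
    probability: float
    task_frequency: float
    task_intensity: float
    ambient_frequency: float
    ambient_intensity: float

    def __post_init__(self):
        if self.duration <= 0:
            raise DataError("job duration must be positive")
        for name in ("probability", "task_frequency", "ambient_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")
        if min(self.task_intensity, self.ambient_intensity, self.start_age) < 0:
            raise DataError("ages and intensities must be non-negative")


def compute_mie(jobs: Sequence[JobRecord], t: float) -> float:
    """Mean index of exposure at age ``t``.

    Duration-weighted mean of d_l * p_l * (f_sl*i_sl + f_al*i_al) over the
    exposed jobs (probability > 0) begun before ``t``, with each duration
    truncated at ``t``.  Returns 0 when no exposed job time has accrued (the
    degenerate sum-of-durations-zero case is mapped to 0 by convention).
    """
    num = 0.0
    den = 0.0
    for j in jobs:
        if j.probability <= 0.0 or j.start_age >= t:
            continue
        d = min(j.start_age + j.duration, t) - j.start_age
        num += d * j.probability * (
            j.task_frequency * j.task_intensity
            + j.ambient_frequency * j.ambient_intensity
        )
        den += d
    return num / den if den > 0 else 0.0


def read_job_history(path) -> dict[object, list[JobRecord]]:
    """Read a job-history CSV (id,job_start,d,p,f_s,i_s,f_a,i_a) per subject."""
    df = pd.read_csv(path)
    cols = ["id", "job_start", "d", "p", "f_s", "i_s", "f_a", "i_a"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataError(f"job history missing columns {sorted(missing)}")
    out: dict[object, list[JobRecord]] = {}
    for sid, g in df.groupby("id", sort=True):
        out[sid] = [
            JobRecord(r.job_start, r.d, r.p, r.f_s, r.i_s, r.f_a, r.i_a)
            for r in g.itertuples()
        ]
    return out
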