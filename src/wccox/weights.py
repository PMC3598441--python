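"""Age-conditional disease probabilities and time-dependent sampling weights.

The weighted Cox model treats a case-control study as a survey sample of the
source population.  Each sampled unit carries a weight over age:

* cases:    w(t) = 1 for all t up to diagnosis (all eligible cases sampled);
* controls: w(t) = (1 - pi(t)) / pi(t) * n_cases(t) / n_controls(t),

where pi(t) is the probability a member of the source population develops the
disease at age t or later given at risk at t, and n_cases(t) / n_controls(t)
count study members with index age >= t (inclusive, so a control's weight is
always well defined up to its own selection age).

pi(t) can be estimated from the enumerated source cohort (nested designs) or
assembled from published age-band incidence rates (population-based designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CaseControlStudy, CountingProcessRecord, DataError


class WeightError(ValueError):
    """Weights undefined (pi = 0, empty risk set, no controls left...)."""


# ---------------------------------------------------------------------------
# pi(t)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiFunction:
    """Right-continuous step function t -> pi(t) in (0, 1].

    ``breakpoints`` are ascending ages; ``values[k]`` applies on
    [breakpoints[k], breakpoints[k+1]).  The last value is carried forward
    beyond the final breakpoint, and the first value is used below the first
    breakpoint (ages before the first band).
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if bp.size != v.size or bp.size == 0:
            raise DataError("breakpoints and values must match and be nonempty")
        if np.any(np.diff(bp) <= 0):
            raise DataError("pi breakpoints must be strictly increasing")
        if np.any(v <= 0) or np.any(v > 1):
            raise DataError("pi values must lie in (0, 1]")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1, 0, None
        )
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IncidenceTable:
    """Ordered, contiguous age bands with incidence rates per 100,000 p-y."""

    lower: np.ndarray          # band lower ages
    upper: np.ndarray          # band upper ages; NaN = open-ended last band
    rate_per_100000: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        r = np.asarray(self.rate_per_100000, dtype=float)
        for name, arr in (("lower", lo), ("upper", up), ("rate", r)):
            object.__setattr__(self, {"lower": "lower", "upper": "upper",
                                      "rate": "rate_per_100000"}[name], arr)
        if not (lo.size == up.size == r.size) or lo.size == 0:
            raise DataError("incidence table columns must align and be nonempty")
        if np.any(r < 0):
            raise DataError("incidence rates must be non-negative")
        if np.any(np.diff(lo) <= 0):
            raise DataError("bands must be ordered by lower age")
        closed = up[:-1]
        if np.any(np.isnan(closed)):
            raise DataError("only the last band may be open-ended")
        if not np.allclose(closed, lo[1:]):
            raise DataError("bands must be contiguous and non-overlapping")

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        """CSV columns lower,upper,rate_per_100000py; empty upper = open band."""
        df = pd.read_csv(path)
        need = {"lower", "upper", "rate_per_100000py"}
        if not need <= set(df.columns):
            raise DataError(f"incidence CSV needs columns {sorted(need)}")
        return cls(
            df["lower"].to_numpy(float),
            pd.to_numeric(df["upper"], errors="coerce").to_numpy(float),
            df["rate_per_100000py"].to_numpy(float),
        )


def pi_from_incidence_table(table: IncidenceTable) -> PiFunction:
    """Convert age-band incidence rates to the cumulative-tail pi(t).

    pi on band k is the sum over bands j >= k of rate_j / 100,000: the chance
    of developing the disease at the band's ages or later.  Constant within
    bands, non-increasing across them.
    """
    tail = np.cumsum(table.rate_per_100000[::-1])[::-1] / 1e5
    if tail[0] <= 0:
        raise WeightError("all incidence rates are zero; pi degenerate")
    # drop trailing all-zero bands (pi=0 there would make weights infinite)
    keep = tail > 0
    return PiFunction(table.lower[keep], tail[keep])


def _cohort_arrays(population: Sequence[CountingProcessRecord]):
    """Per-subject (entry, exit, event) from counting-process records."""
    entry: dict = {}
    exit_: dict = {}
    event: dict = {}
    for r in population:
        entry[r.subject_id] = min(entry.get(r.subject_id, np.inf), r.start)
        if r.stop >= exit_.get(r.subject_id, -np.inf):
            exit_[r.subject_id] = r.stop
        event[r.subject_id] = event.get(r.subject_id, 0) | r.event
    ids = sorted(entry, key=str)
    return (
        np.array([entry[i] for i in ids], float),
        np.array([exit_[i] for i in ids], float),
        np.array([event[i] for i in ids], bool),
    )


def estimate_pi_from_cohort(population: Sequence[CountingProcessRecord], t: float) -> float:
    """pi(t) from an enumerated source cohort.

    The proportion of subjects with an event at age >= t among those at risk
    at t.  Risk at t requires exit age >= t and (with delayed entry) entry
    age < t — left truncation is honoured automatically because the records
    carry their entry ages.
    """
    entry, exit_, event = _cohort_arrays(population)
    at_risk = (exit_ >= t) & (entry < t)
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        raise WeightError(f"empty risk set at age {t}")
    # subjects at risk at t have exit >= t, so their events are all at ages >= t
    return float((event & at_risk).sum() / n_risk)


class CohortPiFunction:
    """pi(t) over all ages from a source cohort, evaluated exactly.

    Callable like :class:`PiFunction`; internally a suffix count over the
    sorted exit ages, so every distinct exit age is a (left-continuous in the
    counting sense, inclusive at t) breakpoint.
    """

    def __init__(self, exit_ages, event, entry_ages=None):
        exit_ages = np.asarray(exit_ages, float)
        event = np.asarray(event, bool)
        order = np.argsort(exit_ages, kind="stable")
        self._exit = exit_ages[order]
        ev = event[order].astype(int)
        self._tail_events = np.concatenate([np.cumsum(ev[::-1])[::-1], [0]])
        self._n = exit_ages.size
        # delayed entry: subjects with entry >= t are not yet at risk at t
        # (entry <= exit always, so #(exit>=t & entry>=t) = #(entry>=t))
        if entry_ages is not None and np.any(np.asarray(entry_ages) > 0):
            entry_ages = np.asarray(entry_ages, float)
            self._entry = np.sort(entry_ages)
            self._entry_ev = np.sort(entry_ages[event])
        else:
            self._entry = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._exit, t, side="left")
        n_risk = self._n - idx
        n_ev = self._tail_events[idx]
        if self._entry is not None:
            n_risk = n_risk - (
                self._entry.size - np.searchsorted(self._entry, t, side="left")
            )
            n_ev = n_ev - (
                self._entry_ev.size - np.searchsorted(self._entry_ev, t, side="left")
            )
        if np.any(n_risk <= 0):
            raise WeightError("empty risk set at some requested age")
        out = n_ev / n_risk
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepWeightFunction:
    """A sampled unit's weight omega(t): right-continuous step function on
    (0, domain_end]."""

    unit_id: object
    breakpoints: np.ndarray
    values: np.ndarray
    domain_end: float

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise WeightError(f"unit {self.unit_id}: weights must be positive finite")
        if np.any(np.diff(bp) <= 0):
            raise DataError("weight breakpoints must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1, 0, None)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out


def _study_counts(study: CaseControlStudy):
    df = study.data
    case_ages = np.sort(df.loc[df["status"] == "case", "index_age"].to_numpy(float))
    ctrl_ages = np.sort(df.loc[df["status"] == "control", "index_age"].to_numpy(float))

    def n_cases(t):
        return case_ages.size - np.searchsorted(case_ages, t, side="left")

    def n_controls(t):
        return ctrl_ages.size - np.searchsorted(ctrl_ages, t, side="left")

    return n_cases, n_controls


def wc_weights(study: CaseControlStudy, pi) -> dict[object, StepWeightFunction]:
    """Time-dependent weight function for every sampled unit of a study.

    ``pi`` is any callable age -> probability (a :class:`PiFunction`,
    :class:`CohortPiFunction`, or ad hoc).  Cases get weight 1 up to their
    diagnosis age.  Controls get (1-pi)/pi * n_cases/n_controls with the
    counts taken inclusively at each age; breakpoints are placed at every
    distinct study index age and every pi breakpoint inside the unit's domain.
    """
    df = study.data
    n_cases, n_controls = _study_counts(study)
    index_ages = np.unique(df["index_age"].to_numpy(float))
    pi_breaks = getattr(pi, "breakpoints", None)

    out: dict[object, StepWeightFunction] = {}
    for row in df.itertuples():
        end = float(row.index_age)
        if row.status == "case":
            out[row.sampled_unit_id] = StepWeightFunction(
                row.sampled_unit_id, np.array([0.0]), np.array([1.0]), end
            )
            continue
        breaks = index_ages[index_ages <= end]
        if pi_breaks is not None:
            extra = np.asarray(pi_breaks, float)
            breaks = np.union1d(breaks, extra[extra <= end])
        breaks = np.union1d(breaks, [0.0])
        # evaluate just inside each interval [b_k, b_{k+1})
        pis = np.asarray(pi(breaks), dtype=float)
        if np.any(pis <= 0):
            bad = breaks[np.asarray(pis) <= 0][0]
            raise WeightError(f"pi(t) = 0 at age {bad}; weight infinite")
        nca = np.array([n_cases(b) for b in breaks], dtype=float)
        nco = np.array([n_controls(b) for b in breaks], dtype=float)
        if np.any(nco[breaks <= end] == 0):
            bad = breaks[nco == 0][0]
            raise WeightError(f"no controls remaining at age {bad}")
        vals = (1.0 - pis) / pis * nca / nco
        # weights must be positive: nca can be 0 below the first case age;
        # such ages never enter a risk-set evaluation but keep the function valid
        vals = np.maximum(vals, 1e-300)
        out[row.sampled_unit_id] = StepWeightFunction(
            row.sampled_unit_id, breaks, vals, end
        )
    return out


def weights_to_frame(weights: Mapping[object, StepWeightFunction]) -> pd.DataFrame:
    """Long-format export (unit_id,start,stop,weight), counting-process style."""
    rows = []
    for uid, w in weights.items():
        stops = np.append(w.breakpoints[1:], w.domain_end)
        for start, stop, val in zip(w.breakpoints, stops, w.values):
            if stop > start:
                rows.append({"unit_id": uid, "start": start, "stop": stop,
                             "weight": val})
    return pd.DataFrame(rows, columns=["unit_id", "start", "stop", "weight"])
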