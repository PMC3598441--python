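"""Synthetic source populations with time-varying occupational exposure.

The generator emulates a population exposed to an occupational agent
(asbestos-like) in which exposure intensity follows a latent-class linear
trend over age:

* Scenario A — 85% constant, 6% highly increasing, 3% moderately
  increasing, 6% moderately decreasing intensity (the mix observed in
  population-based asbestos data);
* Scenario B — 50% highly increasing, 50% moderately decreasing.

Ages at first exposure and exposure durations are lognormal.  Event ages are
generated from a Cox model with time-dependent covariates by the
permutational algorithm: marginal (age, status) pairs are drawn first —
Weibull event ages against independent uniform censoring — then swept in
ascending order and matched to subjects, events with probability
proportional to the partial-likelihood factor exp(x_i(t)'beta) among the
still-unassigned, censorings uniformly.  Matched case-control samples are
drawn by incidence-density (risk-set) sampling with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .data_model import (
    MODEL_COVARIATES,
    CaseControlStudy,
    DataError,
    ExposureTrajectory,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class CalibrationError(RuntimeError):
    """Target event rate unattainable."""


class SamplingError(RuntimeError):
    """Risk-set sampling impossible (empty risk set at a case age)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: per-class slope (fibers/ml per year) and intercept lognormal (mean, sd)
DEFAULT_CLASS_PARAMS = {
    "constant": {"slope": 0.0, "intercept_mean": 0.4, "intercept_sd": 1.1},
    "highly_increasing": {"slope": 0.15, "intercept_mean": 0.2, "intercept_sd": 0.3},
    "moderately_increasing": {"slope": 0.05, "intercept_mean": 0.2, "intercept_sd": 0.4},
    "moderately_decreasing": {"slope": -0.05, "intercept_mean": 1.5, "intercept_sd": 0.8},
}

SCENARIO_CLASS_PROBS = {
    "A": {"constant": 0.85, "highly_increasing": 0.06,
          "moderately_increasing": 0.03, "moderately_decreasing": 0.06},
    "B": {"highly_increasing": 0.50, "moderately_decreasing": 0.50},
}

#: true effects, weak to strong, per covariate (per-unit scale)
TRUE_BETA = {
    "strong": {"intensity": 1.39, "duration": 0.05,
               "age_first_exposure": -0.11, "time_since_last_exposure": 0.04},
    "weak": {"intensity": 0.41, "duration": 0.01,
             "age_first_exposure": -0.01, "time_since_last_exposure": 0.01},
}


def default_beta(model: int, strength: str = "strong") -> dict[str, float]:
    """True coefficient vector for a regression model (1, 2 or 3)."""
    table = TRUE_BETA[strength]
    return {name: table[name] for name in MODEL_COVARIATES[model]}


@dataclass
class SimulationConfig:
    """All knobs of one simulation condition.

    Ages in years, intensities in fibers/ml.  The lognormal moments are on
    the natural scale (mean/sd of the distribution, not of its log).
    """

    population_size: int = 1000
    scenario: str = "A"
    model: int = 1
    beta: dict = field(default_factory=lambda: default_beta(1))
    ratio: int = 1
    target_event_rate: float = 0.10
    weibull_shape: float = 5.0
    weibull_scale: float = 72.0
    age_first_mean: float = 21.0
    age_first_sd: float = 8.0
    duration_mean: float = 27.0
    duration_sd: float = 14.0
    class_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()})
    replications: int = 1000
    master_seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIO_CLASS_PROBS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.model not in MODEL_COVARIATES:
            raise ConfigError(f"model must be in {sorted(MODEL_COVARIATES)}")
        if not 0.0 < self.target_event_rate < 1.0:
            raise ConfigError("target_event_rate must lie in (0, 1)")
        if self.ratio < 1 or self.population_size < 1 or self.replications < 1:
            raise ConfigError("population_size, ratio, replications must be >= 1")
        for v in (self.age_first_mean, self.age_first_sd,
                  self.duration_mean, self.duration_sd,
                  self.weibull_shape, self.weibull_scale):
            if not np.isfinite(v) or v <= 0:
                raise ConfigError("distribution parameters must be positive finite")
        missing = set(MODEL_COVARIATES[self.model]) - set(self.beta)
        if missing:
            raise ConfigError(f"beta missing coefficients {sorted(missing)}")
        probs = SCENARIO_CLASS_PROBS[self.scenario]
        if not np.isclose(sum(probs.values()), 1.0):
            raise ConfigError("class proportions must sum to 1")

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[k] for k in MODEL_COVARIATES[self.model]])

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return MODEL_COVARIATES[self.model]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "beta" not in d:
            d["beta"] = default_beta(int(d.get("model", 1)),
                                     d.pop("effect_strength", "strong"))
        else:
            d.pop("effect_strength", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given natural-scale mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


# ---------------------------------------------------------------------------
# trajectory bank (vectorised exposure histories)
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryBank:
    """Columnar store of clamped-linear exposure trajectories.

    Intensity at age a is max(0, intercept + slope*(a - age_first)) on
    [age_first, age_last], zero outside.  All covariate evaluation is closed
    form and vectorised; scalar :class:`ExposureTrajectory` views are built
    on demand.
    """

    age_first: np.ndarray
    age_last: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray
    pattern_class: np.ndarray  # array of class-name strings

    def __post_init__(self):
        if np.any(self.age_first >= self.age_last):
            raise DataError("age_first must be below age_last for every subject")
        if np.any(self.intercept < 0):
            raise DataError("intensity intercepts must be non-negative")

    def __len__(self) -> int:
        return self.age_first.size

    def cumulated_intensity(self, t: float, idx=None) -> np.ndarray:
        """Exact integral of the clamped-linear profile up to min(t, age_last)."""
        a0 = self.age_first if idx is None else self.age_first[idx]
        a1 = self.age_last if idx is None else self.age_last[idx]
        c = self.intercept if idx is None else self.intercept[idx]
        s = self.slope if idx is None else self.slope[idx]
        w = np.clip(np.minimum(t, a1) - a0, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            x0 = np.where(s < 0, c / np.maximum(-s, 1e-300), np.inf)
        weff = np.minimum(w, x0)  # decreasing profiles stop accruing at 0-crossing
        return weff * (c + s * weff / 2.0)

    def covariates_at(self, t: float, model: int = 1, idx=None) -> np.ndarray:
        """(n, p) covariate matrix at age ``t`` for model 1, 2 or 3."""
        a0 = self.age_first if idx is None else self.age_first[idx]
        a1 = self.age_last if idx is None else self.age_last[idx]
        duration = np.clip(np.minimum(t, a1) - a0, 0.0, None)
        cum = self.cumulated_intensity(t, idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            intensity = np.where(duration > 0, cum / np.maximum(duration, 1e-300), 0.0)
        cols = {"intensity": intensity, "duration": duration,
                "age_first_exposure": a0,
                "time_since_last_exposure": np.clip(t - a1, 0.0, None)}
        return np.column_stack([cols[k] for k in MODEL_COVARIATES[model]])

    def trajectory(self, i: int, subject_id=None) -> ExposureTrajectory:
        return ExposureTrajectory.from_linear(
            subject_id if subject_id is not None else i,
            float(self.age_first[i]), float(self.age_last[i]),
            float(self.intercept[i]), float(self.slope[i]),
            str(self.pattern_class[i]),
        )


class BankTrajectories(Mapping):
    """Read-only Mapping view of a bank: subject index -> ExposureTrajectory."""

    def __init__(self, bank: TrajectoryBank):
        self._bank = bank

    def __getitem__(self, i):
        return self._bank.trajectory(int(i))

    def __iter__(self):
        return iter(range(len(self._bank)))

    def __len__(self):
        return len(self._bank)


def generate_exposure_histories(
    n: int, scenario: str, config: SimulationConfig, rng: np.random.Generator
) -> TrajectoryBank:
    """Draw n exposure trajectories for a scenario's latent-class mixture."""
    if scenario not in SCENARIO_CLASS_PROBS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    classes = list(SCENARIO_CLASS_PROBS[scenario])
    probs = np.array([SCENARIO_CLASS_PROBS[scenario][c] for c in classes])
    mu_a, sg_a = _lognormal_params(config.age_first_mean, config.age_first_sd)
    mu_d, sg_d = _lognormal_params(config.duration_mean, config.duration_sd)
    a0 = rng.lognormal(mu_a, sg_a, n)
    a1 = a0 + rng.lognormal(mu_d, sg_d, n)
    which = rng.choice(len(classes), size=n, p=probs)
    intercept = np.empty(n)
    slope = np.empty(n)
    for ci, cname in enumerate(classes):
        par = config.class_params[cname]
        if par["intercept_mean"] <= 0 or par["intercept_sd"] <= 0:
            raise ConfigError(f"degenerate intercept lognormal for class {cname}")
        mu_c, sg_c = _lognormal_params(par["intercept_mean"], par["intercept_sd"])
        mask = which == ci
        intercept[mask] = rng.lognormal(mu_c, sg_c, int(mask.sum()))
        slope[mask] = par["slope"]
    return TrajectoryBank(a0, a1, intercept, slope,
                          np.array(classes, dtype=object)[which])


# ---------------------------------------------------------------------------
# censoring calibration
# ---------------------------------------------------------------------------


def expected_event_fraction(bound: float, shape: float, scale: float) -> float:
    """P(T <= C) for T ~ Weibull(shape, scale), C ~ Uniform(0, bound).

    Under the permutational algorithm the event/censoring status of each age
    slot is fixed by the marginal (T, C) pair, so the realised event fraction
    does not depend on beta or on the trajectories.  Closed form via the
    lower incomplete gamma function.
    """
    x = (bound / scale) ** shape
    integral_surv = (scale / shape) * special.gamma(1.0 / shape) * \
        special.gammainc(1.0 / shape, x)
    return 1.0 - integral_surv / bound


def calibrate_censoring(
    target_rate: float, weibull_shape: float, weibull_scale: float
) -> float:
    """Uniform censoring bound giving the target expected event fraction.

    Solved by Brent root-finding on the exact expectation; the fraction is
    increasing in the bound (a larger bound censors later, so more event ages
    fall before their censoring age).
    """
    if not 0.0 < target_rate < 1.0:
        raise CalibrationError("target event rate must lie strictly in (0, 1)")
    f = lambda b: expected_event_fraction(b, weibull_shape, weibull_scale) - target_rate
    hi = weibull_scale
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * weibull_scale:
            raise CalibrationError("target event rate unattainable")
    return float(optimize.brentq(f, 1e-9 * weibull_scale, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# permutational event-time assignment
# ---------------------------------------------------------------------------


@dataclass
class SourcePopulation:
    """A generated cohort: trajectories plus per-subject exit age and status."""

    bank: TrajectoryBank
    exit_age: np.ndarray
    event: np.ndarray
    model: int
    censoring_bound: float

    @property
    def n(self) -> int:
        return len(self.bank)

    @property
    def event_rate(self) -> float:
        return float(self.event.mean())


def assign_event_times_permutational(
    bank: TrajectoryBank,
    beta: np.ndarray,
    model: int,
    weibull_shape: float,
    weibull_scale: float,
    censoring_bound: float,
    rng: np.random.Generator,
) -> SourcePopulation:
    """Match marginal (age, status) draws to trajectories, events by
    partial-likelihood probabilities.

    Ages are swept ascending; an event age goes to a still-unassigned subject
    with probability proportional to exp(x_i(t)'beta); a censoring age goes
    to a uniform unassigned subject.  The assigned age multiset equals the
    generated one exactly, and at beta = 0 the assignment is an exchangeable
    permutation.
    """
    n = len(bank)
    beta = np.asarray(beta, float)
    T = weibull_scale * rng.weibull(weibull_shape, n)
    C = rng.uniform(0.0, censoring_bound, n)
    ages = np.minimum(T, C)
    status = T <= C
    order = np.argsort(ages, kind="stable")

    alive = np.arange(n)
    count = n
    exit_age = np.empty(n)
    event = np.empty(n, dtype=bool)
    for k in order:
        t, is_event = float(ages[k]), bool(status[k])
        assert count > 0, "more ages than subjects"
        if is_event:
            x = bank.covariates_at(t, model, idx=alive[:count])
            eta = x @ beta
            eta -= eta.max()
            cdf = np.cumsum(np.exp(eta))
            pos = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
            pos = min(pos, count - 1)
        else:
            pos = int(rng.integers(count))
        subj = alive[pos]
        exit_age[subj] = t
        event[subj] = is_event
        alive[pos] = alive[count - 1]
        count -= 1
    return SourcePopulation(bank, exit_age, event, model, censoring_bound)


def generate_population(config: SimulationConfig, rng: np.random.Generator,
                        censoring_bound: Optional[float] = None) -> SourcePopulation:
    """Trajectories + permutational event times in one call."""
    if censoring_bound is None:
        censoring_bound = calibrate_censoring(
            config.target_event_rate, config.weibull_shape, config.weibull_scale)
    bank = generate_exposure_histories(
        config.population_size, config.scenario, config, rng)
    return assign_event_times_permutational(
        bank, config.beta_vector, config.model,
        config.weibull_shape, config.weibull_scale, censoring_bound, rng)


# ---------------------------------------------------------------------------
# incidence-density case-control sampling
# ---------------------------------------------------------------------------


def sample_case_control(
    population: SourcePopulation, m: int, rng: np.random.Generator
) -> CaseControlStudy:
    """Risk-set sample: every case, plus m controls per case drawn with
    replacement from subjects at risk (exit age >= case age, case excluded).

    Controls inherit the case's event age as their index (selection) age —
    1:m individual matching on age.
    """
    exit_age = population.exit_age
    order = np.argsort(exit_age, kind="stable")
    sorted_exit = exit_age[order]
    case_idx = np.flatnonzero(population.event)
    if case_idx.size == 0:
        raise SamplingError("source population contains no events")
    rows = []
    for set_no, ci in enumerate(case_idx):
        t = float(exit_age[ci])
        start = int(np.searchsorted(sorted_exit, t, side="left"))
        pool = order[start:]
        pool = pool[pool != ci]
        if pool.size == 0:
            raise SamplingError(f"empty risk set at case age {t}")
        picks = pool[rng.integers(0, pool.size, size=m)]
        rows.append({"sampled_unit_id": f"s{set_no}c", "source_subject_id": int(ci),
                     "status": "case", "index_age": t, "set_id": set_no})
        rows.extend(
            {"sampled_unit_id": f"s{set_no}k{j}", "source_subject_id": int(pk),
             "status": "control", "index_age": t, "set_id": set_no}
            for j, pk in enumerate(picks)
        )
    df = pd.DataFrame(rows)
    return CaseControlStudy(df, BankTrajectories(population.bank))


# ---------------------------------------------------------------------------
# counting-process export
# ---------------------------------------------------------------------------


def population_to_counting_process(
    population: SourcePopulation, model: Optional[int] = None
) -> pd.DataFrame:
    """Expand a population into long format split at the event ages.

    Covariates are evaluated at each interval's stop, the value carried on
    (start, stop] under the left-continuous step convention used throughout.
    """
    model = population.model if model is None else model
    names = MODEL_COVARIATES[model]
    cuts = np.unique(population.exit_age[population.event])
    rows = []
    for i in range(population.n):
        e = float(population.exit_age[i])
        stops = np.append(cuts[cuts < e], e)
        starts = np.concatenate([[0.0], stops[:-1]])
        for s, st in zip(starts, stops):
            x = population.bank.covariates_at(st, model, idx=np.array([i]))[0]
            rows.append({"id": i, "start": s, "stop": st,
                         "event": int(population.event[i] and st == e),
                         **dict(zip(names, x))})
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", *names])
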