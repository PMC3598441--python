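"""Replication engine and performance criteria for the simulation study.

One replication = generate a source population, fit the full-cohort
time-dependent Cox oracle, draw an age-matched case-control sample, estimate
pi(t) from the cohort, build the time-dependent weights, and fit the four
case-control analyses: WC1/WC2 (shared point estimates, robust vs
superpopulation standard errors), CLR and ULR.  Across replications the
standard comparison criteria are computed per method and covariate:
relative bias (vs the true beta and vs the full-cohort Cox), empirical
relative efficiency, RMSE, ASE/SDE and 95% CI coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import SeparationError, fit_clr, fit_ulr, index_age_design
from .data_model import MODEL_COVARIATES, CaseControlStudy
from .simulator import (
    SimulationConfig,
    SourcePopulation,
    calibrate_censoring,
    generate_population,
    sample_case_control,
)
from .wc_cox import ConvergenceError, CoxArrays, FitResult, fit_weighted_cox
from .weights import CohortPiFunction, wc_weights

logger = logging.getLogger("wccox")

Z95 = float(stats.norm.ppf(0.975))

METHOD_SE = {"WC1": "robust", "WC2": "superpop", "CLR": "naive",
             "ULR": "naive", "Cox": "naive"}


def replication_rng(master_seed: int, index: int) -> np.random.Generator:
    """Child generator for one replication: fully determined by (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


# ---------------------------------------------------------------------------
# fast fitting paths for simulated data
# ---------------------------------------------------------------------------


def study_cox_arrays(
    study: CaseControlStudy, population: SourcePopulation, pi, model: int
) -> CoxArrays:
    """CoxArrays for a sampled study: covariates from the trajectory bank at
    the case event ages, weights from :func:`wc_weights`, clusters by source
    subject (controls drawn with replacement share a cluster)."""
    df = study.data
    n = len(df)
    src = df["source_subject_id"].to_numpy(int)
    exit_ = df["index_age"].to_numpy(float)
    event = (df["status"] == "case").to_numpy()
    ev_order = np.argsort(exit_[event], kind="stable")
    ev_units = np.flatnonzero(event)[ev_order]
    ev_ages = exit_[ev_units]
    K, p = ev_ages.size, len(MODEL_COVARIATES[model])
    X = np.empty((K, n, p))
    for k, t in enumerate(ev_ages):
        X[k] = population.bank.covariates_at(float(t), model, idx=src)
    wfuncs = wc_weights(study, pi)
    W = np.ones((K, n))
    uids = df["sampled_unit_id"].to_numpy()
    for j in range(n):
        W[:, j] = wfuncs[uids[j]](ev_ages)
    _, cluster = np.unique(src, return_inverse=True)
    return CoxArrays(np.zeros(n), exit_, event, ev_ages, ev_units, X, W,
                     cluster, MODEL_COVARIATES[model])


@dataclass
class CohortFit:
    """Full-cohort Cox fit (weights 1): point estimates and naive variance."""

    beta: np.ndarray
    names: tuple[str, ...]
    info_inverse: np.ndarray
    loglik: float
    iterations: int
    converged: bool

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.info_inverse))


def fit_cohort_cox(
    population: SourcePopulation,
    model: Optional[int] = None,
    tol: float = 1e-9,
    max_iter: int = 25,
) -> CohortFit:
    """Unweighted time-dependent Cox fit on the full source population.

    Streams over event ages (risk sets are suffixes of the exit-age order)
    without materialising the events-by-subjects covariate array, so cohorts
    of tens of thousands fit in memory.  Same estimating equation as
    :func:`wccox.wc_cox.fit_weighted_cox` with weights 1.
    """
    model = population.model if model is None else model
    names = MODEL_COVARIATES[model]
    p = len(names)
    exit_ = population.exit_age
    order = np.argsort(exit_, kind="stable")
    sorted_exit = exit_[order]
    ev_sorted_pos = np.flatnonzero(population.event[order])
    ev_ages = sorted_exit[ev_sorted_pos]
    age_order = np.argsort(ev_ages, kind="stable")
    ev_ages = ev_ages[age_order]
    ev_sorted_pos = ev_sorted_pos[age_order]
    bank = population.bank

    def pass_over(beta):
        U = np.zeros(p)
        info = np.zeros((p, p))
        ll = 0.0
        for t, pos in zip(ev_ages, ev_sorted_pos):
            start = int(np.searchsorted(sorted_exit, t, side="left"))
            idx = order[start:]
            X = bank.covariates_at(float(t), model, idx=idx)
            eta = X @ beta
            c = eta.max()
            r = np.exp(eta - c)
            S0 = r.sum()
            m = (r @ X) / S0
            xi = X[pos - start]
            U += xi - m
            info += np.einsum("n,np,nq->pq", r / S0, X, X) - np.outer(m, m)
            ll += float(eta[pos - start] - c - np.log(S0))
        return U, info, ll

    beta = np.zeros(p)
    U, info, ll = pass_over(beta)
    it = 0
    converged = np.max(np.abs(U)) < tol
    while it < max_iter and not converged:
        it += 1
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information in cohort fit") from exc
        new_beta = beta + step
        U_n, info_n, ll_n = pass_over(new_beta)
        halv = 0
        while (not np.isfinite(ll_n) or ll_n < ll - 1e-12) and halv < 10:
            halv += 1
            step /= 2.0
            new_beta = beta + step
            U_n, info_n, ll_n = pass_over(new_beta)
        rel = np.max(np.abs(step)) / max(1.0, np.max(np.abs(new_beta)))
        beta, U, info, ll = new_beta, U_n, info_n, ll_n
        if np.max(np.abs(U)) < tol or rel < 1e-10:
            converged = np.max(np.abs(U)) < max(tol, 1e-6)
            break
    return CohortFit(beta, names, np.linalg.inv(info), ll, it, bool(converged))


# ---------------------------------------------------------------------------
# replications
# ---------------------------------------------------------------------------


@dataclass
class ReplicationResult:
    """Per-method estimates from one simulated case-control study."""

    index: int
    names: tuple[str, ...]
    cox_beta: np.ndarray
    cox_se: np.ndarray
    wc_beta: Optional[np.ndarray]          # shared by WC1 and WC2
    wc_se_robust: Optional[np.ndarray]
    wc_se_superpop: Optional[np.ndarray]
    wc_se_naive: Optional[np.ndarray]
    clr_beta: Optional[np.ndarray]
    clr_se: Optional[np.ndarray]
    ulr_beta: Optional[np.ndarray]         # exposure covariates only
    ulr_se: Optional[np.ndarray]
    event_rate: float
    n_cases: int
    error: Optional[str] = None


def run_replication(config: SimulationConfig, index: int,
                    censoring_bound: float) -> ReplicationResult:
    rng = replication_rng(config.master_seed, index)
    names = config.covariate_names
    pop = generate_population(config, rng, censoring_bound)
    cox = fit_cohort_cox(pop, config.model)
    study = sample_case_control(pop, config.ratio, rng)
    pi = CohortPiFunction(pop.exit_age, pop.event)
    res = ReplicationResult(
        index=index, names=names, cox_beta=cox.beta, cox_se=cox.se(),
        wc_beta=None, wc_se_robust=None, wc_se_superpop=None, wc_se_naive=None,
        clr_beta=None, clr_se=None, ulr_beta=None, ulr_se=None,
        event_rate=pop.event_rate, n_cases=int(pop.event.sum()),
    )
    errors = []
    try:
        d = study_cox_arrays(study, pop, pi, config.model)
        wc = fit_weighted_cox(d)
        if wc.converged:
            res.wc_beta = wc.beta
            res.wc_se_robust = wc.se("robust")
            res.wc_se_superpop = wc.se("superpop")
            res.wc_se_naive = wc.se("naive")
    except Exception as exc:  # noqa: BLE001 - recorded, never fatal
        errors.append(f"WC: {exc}")
    design = index_age_design(study, config.model)
    try:
        clr = fit_clr(design, names)
        if clr.converged:
            res.clr_beta, res.clr_se = clr.beta, clr.se()
    except (SeparationError, np.linalg.LinAlgError) as exc:
        errors.append(f"CLR: {exc}")
    try:
        ulr = fit_ulr(design, names, include_age=True)
        if ulr.converged:
            res.ulr_beta = ulr.beta[: len(names)]
            res.ulr_se = ulr.se()[: len(names)]
    except (SeparationError, np.linalg.LinAlgError) as exc:
        errors.append(f"ULR: {exc}")
    if errors:
        res.error = "; ".join(errors)
    return res


@dataclass
class ExperimentResult:
    config: SimulationConfig
    replications: list
    censoring_bound: float

    def __iter__(self):
        return iter(self.replications)


def run_experiment(config: SimulationConfig,
                   replications: Optional[int] = None) -> ExperimentResult:
    """Run the configured number of replications; failures are recorded,
    never fatal.  Fully reproducible from (master_seed, replication index)."""
    reps = config.replications if replications is None else replications
    bound = calibrate_censoring(config.target_event_rate, config.weibull_shape,
                                config.weibull_scale)
    out = []
    for i in range(reps):
        try:
            out.append(run_replication(config, i, bound))
        except Exception as exc:  # noqa: BLE001 - per-replication fault isolation
            logger.warning("replication %d failed outright: %s", i, exc)
    n_err = sum(1 for r in out if r.error)
    if n_err:
        logger.info("%d/%d replications had non-converged analyses", n_err, reps)
    return ExperimentResult(config, out, bound)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def _stack(reps, attr) -> tuple[np.ndarray, np.ndarray]:
    """(matrix of rows, boolean availability mask) for a per-rep vector field."""
    rows = [getattr(r, attr) for r in reps]
    ok = np.array([r is not None for r in rows])
    p = len(reps[0].names)
    mat = np.full((len(rows), p), np.nan)
    for i, r in enumerate(rows):
        if r is not None:
            mat[i] = r
    return mat, ok


def compute_metrics(results: ExperimentResult,
                    true_beta: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """The six comparison criteria per method and covariate.

    Empirical variances use the unbiased (n-1) convention.  Coverage uses
    each method's own standard error: WC1 robust, WC2 superpopulation,
    CLR/ULR/Cox naive.  Non-converged replications are excluded per method;
    ``n_converged`` records how many entered.  A zero true beta makes the
    relative bias absolute (flagged in ``bias_is_absolute``).
    """
    reps = results.replications
    if len(reps) < 2:
        raise ValueError("need >= 2 replications for empirical criteria")
    names = reps[0].names
    beta_true = (results.config.beta_vector if true_beta is None
                 else np.asarray(true_beta, float))
    cox_beta, _ = _stack(reps, "cox_beta")
    cox_var = np.var(cox_beta, axis=0, ddof=1)

    sources = {
        "Cox": ("cox_beta", "cox_se"),
        "WC1": ("wc_beta", "wc_se_robust"),
        "WC2": ("wc_beta", "wc_se_superpop"),
        "CLR": ("clr_beta", "clr_se"),
        "ULR": ("ulr_beta", "ulr_se"),
    }
    rows = []
    for method, (b_attr, s_attr) in sources.items():
        B, ok_b = _stack(reps, b_attr)
        S, ok_s = _stack(reps, s_attr)
        ok = ok_b & ok_s
        if ok.sum() < 2:
            continue
        B, S = B[ok], S[ok]
        CB = cox_beta[ok]
        mean_b = B.mean(axis=0)
        var_b = np.var(B, axis=0, ddof=1)
        sde = np.sqrt(var_b)
        covered = (np.abs(B - beta_true) <= Z95 * S).mean(axis=0) * 100.0
        for j, name in enumerate(names):
            absolute = beta_true[j] == 0.0
            rel_bias = (mean_b[j] - beta_true[j]) if absolute else \
                float(np.mean((B[:, j] - beta_true[j]) / beta_true[j]) * 100.0)
            # degenerate inputs (identical estimates, zero Cox beta) give
            # inf/nan ratios rather than warnings
            with np.errstate(divide="ignore", invalid="ignore"):
                rel_bias_cox = float(
                    np.mean((B[:, j] - CB[:, j]) / CB[:, j]) * 100.0)
                rel_eff = float(cox_var[j] / var_b[j]) if var_b[j] > 0 else np.inf
                ase_sde = float(S[:, j].mean() / sde[j]) if sde[j] > 0 else np.inf
            rows.append({
                "method": method, "covariate": name,
                "relative_bias_pct": rel_bias,
                "relative_bias_vs_cox_pct": rel_bias_cox,
                "relative_efficiency": rel_eff,
                "rmse": float(np.sqrt((mean_b[j] - beta_true[j]) ** 2 + var_b[j])),
                "ase_sde": ase_sde,
                "coverage_pct": float(covered[j]),
                "n_converged": int(ok.sum()),
                "bias_is_absolute": bool(absolute),
            })
    return pd.DataFrame(rows)


def report_tables(metrics: pd.DataFrame, csv_path=None, text_path=None) -> str:
    """Render the criteria as CSV plus an aligned text table.

    WC2 shares its point estimates with WC1, so its bias / efficiency / RMSE
    cells are shown as '-' in the text rendering (they differ only through
    the variance estimator).
    """
    if csv_path is not None:
        metrics.to_csv(csv_path, index=False)
    shared = ("relative_bias_pct", "relative_bias_vs_cox_pct",
              "relative_efficiency", "rmse")
    cols = ["method", "covariate", "relative_bias_pct",
            "relative_bias_vs_cox_pct", "relative_efficiency", "rmse",
            "ase_sde", "coverage_pct", "n_converged"]
    header = (f"{'method':<6}{'covariate':<26}{'rel.bias%':>10}"
              f"{'bias/Cox%':>10}{'rel.eff':>9}{'RMSE':>9}{'ASE/SDE':>9}"
              f"{'cover%':>8}{'n':>6}")
    lines = [header, "-" * len(header)]
    for _, r in metrics[cols].iterrows():
        def cell(key, fmt):
            if r["method"] == "WC2" and key in shared:
                return "-"
            return format(r[key], fmt)
        lines.append(
            f"{r['method']:<6}{r['covariate']:<26}"
            f"{cell('relative_bias_pct', '.1f'):>10}"
            f"{cell('relative_bias_vs_cox_pct', '.1f'):>10}"
            f"{cell('relative_efficiency', '.2f'):>9}"
            f"{cell('rmse', '.3f'):>9}"
            f"{r['ase_sde']:>9.2f}{r['coverage_pct']:>8.1f}"
            f"{int(r['n_converged']):>6}"
        )
    text = "\n".join(lines)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(text + "\n")
    return text
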