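"""Weighted Cox pseudo-likelihood with time-dependent covariates and weights.

The estimating equation is the weighted partial-likelihood score

    U(beta) = sum_i w_i(t_i) d_i [ x_i(t_i) - S1(t_i, beta) / S0(t_i, beta) ],

with S0(t) = sum_j w_j(t) Y_j(t) exp(x_j(t)' beta) and S1 its
covariate-weighted counterpart.  Three variance estimators are produced:

* naive      — inverse observed information I(beta)^{-1};
* robust     — Binder's sandwich I^{-1} (sum of squared weighted score
               residuals, clustered) I^{-1}, identically D'D for the
               weighted dfbetas D (Barlow);
* superpopulation — Lin's estimator V2 = V1 + I^{-1}, adding back the
               naive term to account for the source population itself
               being a sample from an infinite superpopulation.

Tied event ages are handled with the Breslow convention (the score above is
simply summed over events).  Data enter either as a :class:`CoxArrays`
container (covariates and weights pre-evaluated at the event ages) or via
:func:`build_cox_arrays` from counting-process long format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 25
MAX_STEP_HALVINGS = 10
DIVERGENCE_BOUND = 50.0


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed (monotone likelihood or singular information)."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class CoxArrays:
    """Risk-set data evaluated at the K event ages.

    entry/exit/event are per sampled unit (n of them); ``X[k, j, :]`` is unit
    j's covariate vector at event age ``event_ages[k]``; ``W[k, j]`` its
    weight there.  ``event_unit[k]`` indexes the unit whose event defines age
    k (ages ascending; ties allowed, Breslow).  ``cluster`` groups sampled
    units from the same source subject for the robust variance.
    """

    entry: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    event_ages: np.ndarray
    event_unit: np.ndarray
    X: np.ndarray
    W: np.ndarray
    cluster: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        K, n, p = self.X.shape
        if self.W.shape != (K, n) or self.event_ages.shape != (K,):
            raise DataError("CoxArrays shapes inconsistent")
        if np.any(np.diff(self.event_ages) < 0):
            raise DataError("event ages must be ascending")
        self.at_risk = (self.entry[None, :] < self.event_ages[:, None]) & (
            self.exit[None, :] >= self.event_ages[:, None]
        )
        if not self.at_risk.any(axis=1).all():
            k = int(np.flatnonzero(~self.at_risk.any(axis=1))[0])
            raise DataError(f"empty risk set at event age {self.event_ages[k]}")

    @property
    def n_units(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return self.event_ages.size

    @property
    def n_params(self) -> int:
        return self.X.shape[2]


def build_cox_arrays(
    data: pd.DataFrame,
    weights: Optional[pd.DataFrame] = None,
    cluster: Optional[Mapping] = None,
    covariates: Optional[Sequence[str]] = None,
) -> CoxArrays:
    """Assemble :class:`CoxArrays` from counting-process long format.

    ``data`` has columns id,start,stop,event plus covariate columns (interval-
    constant on (start, stop]); ``weights`` optionally unit_id,start,stop,weight
    in the same convention (missing units default to weight 1).
    """
    req = {"id", "start", "stop", "event"}
    if not req <= set(data.columns):
        raise DataError(f"counting-process frame needs columns {sorted(req)}")
    if covariates is None:
        covariates = [c for c in data.columns if c not in req]
    ids, entry, exit_, event, event_age = [], [], [], [], []
    per_unit = {}
    for uid, g in data.groupby("id", sort=True):
        g = g.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["stop"].to_numpy()[:-1] - 1e-12).any():
            raise DataError(f"subject {uid}: overlapping intervals")
        ids.append(uid)
        entry.append(float(g["start"].iloc[0]))
        exit_.append(float(g["stop"].iloc[-1]))
        ev = int(g["event"].sum())
        if ev > 1:
            raise DataError(f"subject {uid}: more than one event")
        event.append(bool(ev))
        if ev:
            event_age.append(float(g.loc[g["event"] == 1, "stop"].iloc[0]))
        per_unit[uid] = (
            g["stop"].to_numpy(float),
            g[list(covariates)].to_numpy(float),
        )
    entry = np.array(entry)
    exit_ = np.array(exit_)
    event = np.array(event, bool)
    ev_units = np.flatnonzero(event)
    ev_ages = np.array(
        [a for _, a in sorted(zip(ev_units, event_age))], dtype=float
    )
    order = np.argsort(ev_ages, kind="stable")
    ev_ages = ev_ages[order]
    ev_units = ev_units[order]
    n, K, p = len(ids), ev_ages.size, len(covariates)
    X = np.zeros((K, n, p))
    for j, uid in enumerate(ids):
        stops, covs = per_unit[uid]
        # interval (start, stop] covering t: first stop >= t
        idx = np.clip(np.searchsorted(stops, ev_ages, side="left"), 0, len(stops) - 1)
        X[:, j, :] = covs[idx]
    W = np.ones((K, n))
    if weights is not None:
        for uid, g in weights.groupby("unit_id", sort=False):
            if uid not in per_unit:
                continue
            j = ids.index(uid)
            stops = g["stop"].to_numpy(float)
            vals = g["weight"].to_numpy(float)
            idx = np.clip(np.searchsorted(stops, ev_ages, side="left"), 0,
                          len(stops) - 1)
            W[:, j] = vals[idx]
    if cluster is None:
        clus = np.arange(n)
    else:
        labels = [cluster.get(uid, uid) for uid in ids]
        _, clus = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    return CoxArrays(entry, exit_, event, ev_ages, ev_units, X, W, clus,
                     tuple(covariates))


# ---------------------------------------------------------------------------
# risk-set sums, score, information
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskSetSums:
    S0: float
    S1: np.ndarray
    S2: np.ndarray


def _risk_terms(d: CoxArrays, beta: np.ndarray):
    """r[k, j] = w_j(t_k) Y_j(t_k) exp(x_j(t_k)'beta - c_k) plus sums.

    eta is centred per event age by its at-risk maximum for overflow safety;
    only the ratios r/S0 and log S0 (+ centre) are ever used.
    """
    eta = d.X @ beta                                   # (K, n)
    eta_masked = np.where(d.at_risk, eta, -np.inf)
    centre = eta_masked.max(axis=1)                    # (K,)
    r = np.where(d.at_risk, d.W * np.exp(eta - centre[:, None]), 0.0)
    S0 = r.sum(axis=1)                                 # (K,)
    S1 = np.einsum("kn,knp->kp", r, d.X)               # (K, p)
    return eta, centre, r, S0, S1


def risk_set_sums(d: CoxArrays, beta, t: float) -> RiskSetSums:
    """S0, S1, S2 at event age ``t`` (must be one of the container's ages)."""
    beta = np.asarray(beta, float)
    hits = np.flatnonzero(np.isclose(d.event_ages, t))
    if hits.size == 0:
        raise DataError(f"age {t} is not an evaluated event age")
    k = int(hits[0])
    eta = d.X[k] @ beta
    r = np.where(d.at_risk[k], d.W[k] * np.exp(eta), 0.0)
    S0 = float(r.sum())
    S1 = r @ d.X[k]
    S2 = np.einsum("n,np,nq->pq", r, d.X[k], d.X[k])
    return RiskSetSums(S0, S1, S2)


def pseudo_score(d: CoxArrays, beta) -> np.ndarray:
    """U(beta): weighted sum over events of covariate minus risk-set mean."""
    beta = np.asarray(beta, float)
    _, _, r, S0, S1 = _risk_terms(d, beta)
    m = S1 / S0[:, None]
    wcase = d.W[np.arange(d.n_events), d.event_unit]
    xi = d.X[np.arange(d.n_events), d.event_unit]
    return (wcase[:, None] * (xi - m)).sum(axis=0)


def _score_info_loglik(d: CoxArrays, beta: np.ndarray):
    eta, centre, r, S0, S1 = _risk_terms(d, beta)
    m = S1 / S0[:, None]                               # (K, p)
    karange = np.arange(d.n_events)
    wcase = d.W[karange, d.event_unit]                 # (K,)
    xi = d.X[karange, d.event_unit]                    # (K, p)
    U = (wcase[:, None] * (xi - m)).sum(axis=0)
    S2_over_S0 = np.einsum("kn,knp,knq->kpq", r / S0[:, None], d.X, d.X)
    V = S2_over_S0 - np.einsum("kp,kq->kpq", m, m)     # risk-set covariance
    info = np.einsum("k,kpq->pq", wcase, V)
    loglik = float((wcase * (eta[karange, d.event_unit] - centre - np.log(S0))).sum())
    return U, info, loglik, m, r, S0


def weighted_log_pseudolikelihood(d: CoxArrays, beta) -> float:
    beta = np.asarray(beta, float)
    return _score_info_loglik(d, beta)[2]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted weighted Cox model with all three variance estimators."""

    beta: np.ndarray
    names: tuple[str, ...]
    info_inverse: np.ndarray     # naive variance
    V1: np.ndarray               # robust sandwich
    V2: np.ndarray               # superpopulation (Lin): V1 + I^{-1}
    loglik: float
    score_norm: float
    iterations: int
    converged: bool
    residuals: np.ndarray = field(repr=False, default=None)

    def se(self, which: str = "superpop") -> np.ndarray:
        V = {"naive": self.info_inverse, "robust": self.V1,
             "superpop": self.V2}[which]
        return np.sqrt(np.diag(V))

    def to_dict(self) -> dict:
        out = {"converged": bool(self.converged),
               "iterations": int(self.iterations),
               "loglik": self.loglik, "coefficients": {}}
        for i, name in enumerate(self.names):
            lo1, hi1 = wald_ci(self, which="robust")[i]
            lo2, hi2 = wald_ci(self, which="superpop")[i]
            out["coefficients"][name] = {
                "beta": float(self.beta[i]),
                "hr": float(np.exp(self.beta[i])),
                "se_naive": float(self.se("naive")[i]),
                "se_robust": float(self.se("robust")[i]),
                "se_superpop": float(self.se("superpop")[i]),
                "ci95_robust": [float(lo1), float(hi1)],
                "ci95_superpop": [float(lo2), float(hi2)],
            }
        return out

    def summary(self) -> str:
        lines = [f"weighted Cox fit: {len(self.names)} covariates, "
                 f"{self.iterations} iterations, "
                 f"{'converged' if self.converged else 'NOT converged'}",
                 f"log pseudo-likelihood {self.loglik:.4f}",
                 f"{'covariate':<26}{'beta':>10}{'se(naive)':>11}"
                 f"{'se(robust)':>11}{'se(superpop)':>13}"]
        for i, name in enumerate(self.names):
            lines.append(
                f"{name:<26}{self.beta[i]:>10.4f}{self.se('naive')[i]:>11.4f}"
                f"{self.se('robust')[i]:>11.4f}{self.se('superpop')[i]:>13.4f}"
            )
        return "\n".join(lines)


def fit_weighted_cox(
    d: CoxArrays,
    init: Optional[np.ndarray] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Newton-Raphson with step-halving on the weighted log pseudo-likelihood.

    Converged iff max|U(beta)| < tol or the relative beta change drops below
    1e-10 with a vanishing score trend.  Divergence (monotone likelihood) and
    singular information raise :class:`ConvergenceError`.
    """
    p = d.n_params
    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()
    U, info, ll, *_ = _score_info_loglik(d, beta)
    it = 0
    converged = np.max(np.abs(U)) < tol
    while it < max_iter and not converged:
        it += 1
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta + step
        U_new, info_new, ll_new, *_ = _score_info_loglik(d, new_beta)
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and \
                halvings < MAX_STEP_HALVINGS:
            halvings += 1
            step = step / 2.0
            new_beta = beta + step
            U_new, info_new, ll_new, *_ = _score_info_loglik(d, new_beta)
        rel_change = np.max(np.abs(step)) / max(1.0, np.max(np.abs(new_beta)))
        beta, U, info, ll = new_beta, U_new, info_new, ll_new
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND and np.max(np.abs(U)) > tol:
            raise ConvergenceError(
                "estimate diverging with non-vanishing score (monotone likelihood?)"
            )
        if np.max(np.abs(U)) < tol or rel_change < 1e-10:
            converged = np.max(np.abs(U)) < max(tol, 1e-6)
            break
    if not converged and np.max(np.abs(U)) > max(tol, 1e-6):
        raise ConvergenceError(
            f"no convergence in {it} iterations (max|U| = {np.max(np.abs(U)):.3g}); "
            "monotone likelihood or ill-conditioned design"
        )
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information at the optimum") from exc
    fit = FitResult(beta=beta, names=d.names, info_inverse=info_inv,
                    V1=np.zeros((p, p)), V2=np.zeros((p, p)), loglik=ll,
                    score_norm=float(np.max(np.abs(U))), iterations=it,
                    converged=bool(converged))
    resid = score_residuals(fit, d)
    fit.residuals = resid
    fit.V1 = robust_variance(fit, resid, d)
    fit.V2 = superpop_variance(fit)
    return fit


# ---------------------------------------------------------------------------
# residuals and variances
# ---------------------------------------------------------------------------


def score_residuals(fit: FitResult, d: CoxArrays) -> np.ndarray:
    """Weighted score residual rows (one per sampled unit).

    Row i is the unit's contribution to the pseudo-score: the event term
    w_i(t_i) d_i (x_i(t_i) - m(t_i)) minus, at every event age where the unit
    is at risk, its weighted share of the risk-set mean shift
    w_case(t_k) [w_i(t_k) exp(x_i(t_k)'b) / S0(t_k)] (x_i(t_k) - m(t_k)).
    The unit's own weight enters at each evaluation age, so the rows sum
    exactly to U(beta-hat).
    """
    beta = fit.beta
    _, _, r, S0, S1 = _risk_terms(d, beta)
    m = S1 / S0[:, None]
    karange = np.arange(d.n_events)
    wcase = d.W[karange, d.event_unit]
    resid = np.zeros((d.n_units, d.n_params))
    xi = d.X[karange, d.event_unit]
    np.add.at(resid, d.event_unit, wcase[:, None] * (xi - m))
    frac = (wcase / S0)[:, None] * r                   # (K, n)
    resid -= np.einsum("kn,knp->np", frac, d.X - m[:, None, :])
    return resid


def robust_variance(
    fit: FitResult, residuals: np.ndarray, d: CoxArrays, omega_power: int = 2
) -> np.ndarray:
    """Binder/Barlow sandwich variance V1 = D'D.

    D's rows are the cluster-aggregated weighted score residuals times the
    inverse information (the dfbetas).  Sampled units sharing a source subject
    (controls drawn with replacement) are summed into one cluster row first.

    ``omega_power=2`` (default) squares the weighted residuals, the dfbetas
    identity; ``omega_power=1`` uses one power of the unit's weight at its
    exit age on the outer product of unweighted residuals, the literal reading
    of the printed middle term.
    """
    if omega_power == 2:
        rows = residuals
    elif omega_power == 1:
        w_exit = _weight_at_exit(d)
        rows = (residuals / w_exit[:, None]) * np.sqrt(w_exit)[:, None]
    else:
        raise ValueError("omega_power must be 1 or 2")
    G = np.zeros((int(d.cluster.max()) + 1, d.n_params))
    np.add.at(G, d.cluster, rows)
    D = G @ fit.info_inverse
    return D.T @ D


def _weight_at_exit(d: CoxArrays) -> np.ndarray:
    """Each unit's weight at the last event age at which it is at risk."""
    w = np.ones(d.n_units)
    for j in range(d.n_units):
        ks = np.flatnonzero(d.at_risk[:, j])
        if ks.size:
            w[j] = d.W[ks[-1], j]
    return w


def superpop_variance(fit: FitResult) -> np.ndarray:
    """Lin's superpopulation variance: V2 = V1 + I^{-1} (exact matrix sum)."""
    return fit.V1 + fit.info_inverse


def wald_ci(fit: FitResult, level: float = 0.95, which: str = "superpop") -> np.ndarray:
    """Per-coefficient Wald intervals beta +/- z * se, shape (p, 2)."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se(which)
    return np.column_stack([fit.beta - z * se, fit.beta + z * se])


def hazard_ratio(beta: float, increment: float = 1.0) -> float:
    """HR for an ``increment``-unit increase of a covariate: exp(beta * increment)."""
    return float(np.exp(beta * increment))
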