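"""Standard logistic-regression comparators on index-age-frozen covariates.

The conventional analyses of a matched case-control study ignore the
exposure dynamics: covariates are fixed at their value at the index age
(diagnosis for cases, selection for controls).  Two comparators:

* CLR — conditional logistic regression on the 1:m matched sets, the
  one-case-per-set conditional likelihood maximised by Newton-Raphson;
* ULR — unconditional logistic regression with index age entering as an
  additional continuous covariate (linear on the logit), via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import CaseControlStudy, DataError, exposure_covariates_at, MODEL_COVARIATES

SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """Monotone logistic likelihood (complete or quasi-complete separation)."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    names: tuple[str, ...]
    cov: np.ndarray              # inverse observed information
    converged: bool
    method: str                  # 'CLR' | 'ULR'
    iterations: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def index_age_design(study: CaseControlStudy, model: int = 1) -> pd.DataFrame:
    """One row per sampled unit with covariates frozen at the index age."""
    rows = []
    for r in study.data.itertuples():
        traj = study.trajectories.get(r.source_subject_id)
        if traj is None:
            raise DataError(f"no trajectory for source subject {r.source_subject_id}")
        covs = exposure_covariates_at(traj, float(r.index_age), model)
        rows.append({"sampled_unit_id": r.sampled_unit_id, "set_id": r.set_id,
                     "y": int(r.status == "case"), "age": float(r.index_age),
                     **covs})
    names = MODEL_COVARIATES[model]
    return pd.DataFrame(rows, columns=["sampled_unit_id", "set_id", "y", "age",
                                       *names])


def _design_matrices(design: pd.DataFrame, covariates: Optional[Sequence[str]]):
    if covariates is None:
        covariates = [c for c in design.columns
                      if c not in ("sampled_unit_id", "set_id", "y", "age")]
    X = design[list(covariates)].to_numpy(float)
    y = design["y"].to_numpy(int)
    return X, y, tuple(covariates)


def fit_clr(
    design: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> LogisticFit:
    """Conditional logistic regression, one case per matched set.

    The conditional likelihood contribution of a set is the softmax
    probability that the case, rather than one of its matched controls,
    is the event: exp(x_case'b) / sum_set exp(x_j'b).  Sets without
    covariate discordance contribute a constant and drop out naturally.
    """
    X, y, names = _design_matrices(design, covariates)
    sets = design["set_id"].to_numpy()
    _, g = np.unique(sets, return_inverse=True)
    G = g.max() + 1
    if not np.all(np.bincount(g[y == 1], minlength=G) == 1):
        raise DataError("CLR requires exactly one case per matched set")
    case_rows = np.flatnonzero(y == 1)
    p = X.shape[1]
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        gmax = np.full(G, -np.inf)
        np.maximum.at(gmax, g, eta)
        e = np.exp(eta - gmax[g])
        S0 = np.bincount(g, weights=e, minlength=G)
        P = e / S0[g]
        mean_g = np.zeros((G, p))
        np.add.at(mean_g, g, P[:, None] * X)
        score = X[case_rows].sum(axis=0) - mean_g.sum(axis=0)
        info = np.einsum("n,np,nq->pq", P, X, X) - mean_g.T @ mean_g
        ll = float((eta[case_rows] - (np.log(S0) + gmax)[g[case_rows]]).sum())
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information in CLR") from exc
        halv = 0
        while halv < 10:
            cand = beta + step
            eta_c = X @ cand
            gmax_c = np.full(G, -np.inf)
            np.maximum.at(gmax_c, g, eta_c)
            e_c = np.exp(eta_c - gmax_c[g])
            S0_c = np.bincount(g, weights=e_c, minlength=G)
            ll_c = float((eta_c[case_rows] - (np.log(S0_c) + gmax_c)[g[case_rows]]).sum())
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step /= 2.0
            halv += 1
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BOUND and \
                np.max(np.abs(score)) > max(1e3 * tol, 1e-8):
            raise SeparationError("CLR estimate diverging: one-signed discordance")
    eta = X @ beta
    gmax = np.full(G, -np.inf)
    np.maximum.at(gmax, g, eta)
    e = np.exp(eta - gmax[g])
    S0 = np.bincount(g, weights=e, minlength=G)
    P = e / S0[g]
    mean_g = np.zeros((G, p))
    np.add.at(mean_g, g, P[:, None] * X)
    score = X[case_rows].sum(axis=0) - mean_g.sum(axis=0)
    info = np.einsum("n,np,nq->pq", P, X, X) - mean_g.T @ mean_g
    converged = bool(np.max(np.abs(score)) < max(tol, 1e-6))
    return LogisticFit(beta, names, np.linalg.inv(info), converged, "CLR", it)


def fit_ulr(
    design: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    include_age: bool = True,
) -> LogisticFit:
    """Unconditional logistic regression with intercept (+ linear age)."""
    X, y, names = _design_matrices(design, covariates)
    cols = list(names)
    if include_age:
        X = np.column_stack([X, design["age"].to_numpy(float)])
        cols.append("age")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparation variants
        raise SeparationError(str(exc)) from exc
    beta_full = np.asarray(res.params)
    if np.max(np.abs(beta_full)) > SEPARATION_BOUND and \
            np.max(np.abs(res.model.score(res.params))) > 1e-4:
        raise SeparationError("ULR estimate diverging")
    cov_full = np.asarray(res.cov_params())
    # drop the intercept row/col; keep exposure covariates (+ age)
    keep = np.arange(1, beta_full.size)
    return LogisticFit(beta_full[keep], tuple(cols), cov_full[np.ix_(keep, keep)],
                       bool(res.mle_retvals.get("converged", True)), "ULR",
                       int(res.mle_retvals.get("iterations", 0)))
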