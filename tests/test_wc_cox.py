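import numpy as np
import pandas as pd
import pytest

from wccox.wc_cox import (
    ConvergenceError,
    CoxArrays,
    FitResult,
    build_cox_arrays,
    fit_weighted_cox,
    hazard_ratio,
    pseudo_score,
    risk_set_sums,
    robust_variance,
    score_residuals,
    superpop_variance,
    wald_ci,
    weighted_log_pseudolikelihood,
)


def simple_arrays(exit_, event, x, w=None, cluster=None, names=None):
    """CoxArrays for units with time-constant covariates and weights."""
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != exit_.size:
        x = x.T
    n, p = x.shape
    ev_units = np.flatnonzero(event)
    order = np.argsort(exit_[ev_units], kind="stable")
    ev_units = ev_units[order]
    ev_ages = exit_[ev_units]
    X = np.broadcast_to(x, (ev_ages.size, n, p)).copy()
    W = np.ones((ev_ages.size, n)) if w is None else \
        np.broadcast_to(np.asarray(w, float), (ev_ages.size, n)).copy()
    cluster = np.arange(n) if cluster is None else np.asarray(cluster)
    names = tuple(names or [f"x{i}" for i in range(p)])
    return CoxArrays(np.zeros(n), exit_, event, ev_ages, ev_units, X, W,
                     cluster, names)


def loop_score(d, beta):
    """Independent double-loop evaluation of the weighted score."""
    beta = np.asarray(beta, float)
    U = np.zeros(d.n_params)
    for k in range(d.n_events):
        i = d.event_unit[k]
        s0, s1 = 0.0, np.zeros(d.n_params)
        for j in range(d.n_units):
            if d.at_risk[k, j]:
                r = d.W[k, j] * np.exp(d.X[k, j] @ beta)
                s0 += r
                s1 += r * d.X[k, j]
        U += d.W[k, i] * (d.X[k, i] - s1 / s0)
    return U


def loop_residuals(d, beta):
    """Independent per-unit evaluation of the weighted score residuals."""
    beta = np.asarray(beta, float)
    out = np.zeros((d.n_units, d.n_params))
    for k in range(d.n_events):
        i = d.event_unit[k]
        s0, s1 = 0.0, np.zeros(d.n_params)
        for j in range(d.n_units):
            if d.at_risk[k, j]:
                r = d.W[k, j] * np.exp(d.X[k, j] @ beta)
                s0 += r
                s1 += r * d.X[k, j]
        m = s1 / s0
        out[i] += d.W[k, i] * (d.X[k, i] - m)
        for j in range(d.n_units):
            if d.at_risk[k, j]:
                frac = d.W[k, j] * np.exp(d.X[k, j] @ beta) / s0
                out[j] -= d.W[k, i] * frac * (d.X[k, j] - m)
    return out


def random_instance(rng, n=40, p=2, weighted=True):
    exit_ = rng.uniform(1, 10, n)
    event = rng.random(n) < 0.4
    event[0] = True
    x = rng.normal(size=(n, p))
    w = rng.uniform(0.5, 4.0, n) if weighted else None
    return simple_arrays(exit_, event, x, w)


class TestRiskSetSums:
    def test_two_units_beta_zero(self):
        d = simple_arrays([5.0, 6.0], [True, False], [[0.0], [1.0]])
        s = risk_set_sums(d, [0.0], 5.0)
        assert s.S0 == 2.0 and s.S1[0] == 1.0

    def test_weighted_count(self):
        d = simple_arrays([5.0, 6.0], [True, False], [[0.0], [1.0]], w=[1.0, 3.0])
        s = risk_set_sums(d, [0.0], 5.0)
        assert s.S0 == 4.0 and s.S1[0] == 3.0

    def test_matches_loop_oracle(self, rng):
        d = random_instance(rng)
        beta = rng.normal(size=2) * 0.5
        t = d.event_ages[d.n_events // 2]
        k = int(np.flatnonzero(np.isclose(d.event_ages, t))[0])
        s = risk_set_sums(d, beta, t)
        s0 = sum(d.W[k, j] * np.exp(d.X[k, j] @ beta)
                 for j in range(d.n_units) if d.at_risk[k, j])
        assert s.S0 == pytest.approx(s0, rel=1e-12)

    def test_mean_in_convex_hull(self, rng):
        d = random_instance(rng)
        s = risk_set_sums(d, [0.3, -0.2], d.event_ages[0])
        m = s.S1 / s.S0
        k = 0
        risk_x = d.X[k][d.at_risk[k]]
        assert np.all(m >= risk_x.min(axis=0) - 1e-12)
        assert np.all(m <= risk_x.max(axis=0) + 1e-12)


class TestPseudoScore:
    def test_symmetric_pair_zero_score(self):
        d = simple_arrays([5.0, 5.0], [True, False], [[1.3], [1.3]])
        assert pseudo_score(d, [0.0])[0] == pytest.approx(0.0, abs=1e-14)

    def test_matches_loop_oracle(self, rng):
        d = random_instance(rng)
        beta = rng.normal(size=2) * 0.3
        np.testing.assert_allclose(pseudo_score(d, beta), loop_score(d, beta),
                                   rtol=1e-10, atol=1e-12)

    def test_stationarity_at_fit(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        assert np.max(np.abs(pseudo_score(d, fit.beta))) < 1e-8


class TestFit:
    def test_exchangeable_gives_zero(self):
        # mirror-symmetric design: swapping covariate labels swaps case and
        # control roles, so the score is an odd function of beta
        d = simple_arrays([4.0, 4.5, 5.0, 5.5], [True, False, True, False],
                          [[1.0], [0.0], [0.0], [1.0]])
        fit = fit_weighted_cox(d)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_grid_search_oracle(self):
        # 3 units, fixed weights: compare with an explicit grid maximiser
        d = simple_arrays([2.0, 3.0, 5.0], [True, True, False],
                          [[1.0], [0.0], [0.6]], w=[1.0, 2.5, 0.7])
        grid = np.arange(-2.0, 2.0, 1e-6)
        # explicit weighted log pseudo-likelihood over the grid (vectorised)
        x = np.array([1.0, 0.0, 0.6])
        w = np.array([1.0, 2.5, 0.7])
        eta = np.outer(grid, x)
        r = w * np.exp(eta)
        ll = (w[0] * (eta[:, 0] - np.log(r.sum(axis=1)))
              + w[1] * (eta[:, 1] - np.log(r[:, 1] + r[:, 2])))
        oracle = grid[np.argmax(ll)]
        fit = fit_weighted_cox(d)
        assert fit.beta[0] == pytest.approx(oracle, abs=5e-6)

    def test_unweighted_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 80
        exit_ = rng.uniform(1, 20, n)
        event = rng.random(n) < 0.45
        event[:2] = True
        x = rng.normal(size=(n, 2))
        d = simple_arrays(exit_, event, x)
        fit = fit_weighted_cox(d)
        df = pd.DataFrame({"T": exit_, "E": event.astype(int),
                           "x0": x[:, 0], "x1": x[:, 1]})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(np.diag(fit.info_inverse),
                                   np.diag(cph.variance_matrix_), atol=1e-6)

    def test_time_varying_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        # two intervals per unit with a covariate jump at t=5
        n = 60
        exit_ = rng.uniform(1, 12, n)
        event = rng.random(n) < 0.5
        event[:2] = True
        x_a = rng.normal(size=n)
        x_b = x_a + rng.normal(size=n) * 0.7
        rows = []
        for i in range(n):
            if exit_[i] <= 5.0:
                rows.append({"id": i, "start": 0.0, "stop": exit_[i],
                             "event": int(event[i]), "x": x_a[i]})
            else:
                rows.append({"id": i, "start": 0.0, "stop": 5.0, "event": 0,
                             "x": x_a[i]})
                rows.append({"id": i, "start": 5.0, "stop": exit_[i],
                             "event": int(event[i]), "x": x_b[i]})
        df = pd.DataFrame(rows)
        d = build_cox_arrays(df)
        fit = fit_weighted_cox(d)
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", event_col="event", start_col="start",
                stop_col="stop")
        np.testing.assert_allclose(fit.beta, ctv.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(np.diag(fit.info_inverse),
                                   np.diag(ctv.variance_matrix_), atol=1e-6)

    def test_weight_scaling_leaves_beta(self, rng):
        d = random_instance(rng)
        fit1 = fit_weighted_cox(d)
        d2 = CoxArrays(d.entry, d.exit, d.event, d.event_ages, d.event_unit,
                       d.X, 3.7 * d.W, d.cluster, d.names)
        fit2 = fit_weighted_cox(d2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-9)
        # the dfbetas sandwich is scale-free; the naive variance scales 1/c,
        # so the superpopulation variance is NOT invariant
        np.testing.assert_allclose(fit1.V1, fit2.V1, rtol=1e-8)
        np.testing.assert_allclose(fit1.info_inverse, 3.7 * fit2.info_inverse,
                                   rtol=1e-8)
        assert not np.allclose(fit1.V2, fit2.V2)

    def test_likelihood_ascent(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        assert fit.loglik >= weighted_log_pseudolikelihood(d, np.zeros(2)) - 1e-12

    def test_monotone_likelihood_raises(self):
        # perfectly separating covariate: event units all larger x; the
        # small gap keeps the score from vanishing before beta diverges
        d = simple_arrays([1.0, 2.0, 8.0, 9.0], [True, True, False, False],
                          [[0.1], [0.1], [-0.1], [-0.1]])
        with pytest.raises(ConvergenceError):
            fit_weighted_cox(d)

    def test_breslow_handles_tied_event_ages(self):
        d = simple_arrays([4.0, 4.0, 9.0], [True, True, False],
                          [[1.0], [0.0], [0.5]])
        fit = fit_weighted_cox(d)
        assert fit.converged and np.isfinite(fit.beta[0])


class TestResidualsAndVariances:
    def test_rows_sum_to_score(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        resid = score_residuals(fit, d)
        np.testing.assert_allclose(resid.sum(axis=0), np.zeros(2), atol=1e-8)

    def test_only_at_risk_units_nonzero(self):
        d = simple_arrays([5.0, 6.0, 3.0], [True, False, False],
                          [[1.0], [0.2], [0.9]])
        fit = fit_weighted_cox(d)
        resid = score_residuals(fit, d)
        assert np.all(resid[2] == 0.0)  # exited before the only event

    def test_matches_loop_oracle(self, rng):
        d = random_instance(rng, n=12)
        fit = fit_weighted_cox(d)
        np.testing.assert_allclose(score_residuals(fit, d),
                                   loop_residuals(d, fit.beta),
                                   rtol=1e-9, atol=1e-11)

    def test_robust_scalar_hand_computation(self):
        d = simple_arrays([2.0, 4.0], [True, False], [[1.0], [0.0]],
                          w=[1.0, 2.0])
        fit = fit_weighted_cox(d)
        resid = score_residuals(fit, d)
        info = np.linalg.inv(fit.info_inverse)[0, 0]
        expected = float((resid[:, 0] ** 2).sum()) / info ** 2
        assert robust_variance(fit, resid, d)[0, 0] == pytest.approx(expected)

    def test_dfbetas_equals_explicit_sandwich(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        resid = score_residuals(fit, d)
        G = np.zeros((d.n_units, d.n_params))
        np.add.at(G, d.cluster, resid)
        middle = sum(np.outer(g, g) for g in G)
        explicit = fit.info_inverse @ middle @ fit.info_inverse
        np.testing.assert_allclose(fit.V1, explicit, atol=1e-10)

    def test_v1_psd_symmetric(self, rng):
        for _ in range(5):
            d = random_instance(rng)
            fit = fit_weighted_cox(d)
            assert np.allclose(fit.V1, fit.V1.T)
            assert np.all(np.linalg.eigvalsh(fit.V1) >= -1e-12)

    def test_unweighted_robust_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 70
        exit_ = rng.uniform(1, 20, n)
        event = rng.random(n) < 0.4
        event[:2] = True
        x = rng.normal(size=(n, 2))
        cl = np.arange(n) % (n // 2)  # pairs of units share a cluster
        d = simple_arrays(exit_, event, x, cluster=cl)
        fit = fit_weighted_cox(d)
        df = pd.DataFrame({"T": exit_, "E": event.astype(int), "x0": x[:, 0],
                           "x1": x[:, 1], "cl": cl})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E", robust=True,
                cluster_col="cl")
        # lifelines keeps the naive matrix in variance_matrix_ even when
        # robust=True; the sandwich variance is standard_errors_**2
        np.testing.assert_allclose(np.diag(fit.V1),
                                   cph.standard_errors_.to_numpy() ** 2,
                                   atol=1e-6)

    def test_omega_power_variants_differ(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        v2 = robust_variance(fit, fit.residuals, d, omega_power=2)
        v1 = robust_variance(fit, fit.residuals, d, omega_power=1)
        assert not np.allclose(v1, v2)
        with pytest.raises(ValueError):
            robust_variance(fit, fit.residuals, d, omega_power=3)

    def test_superpop_identity(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        np.testing.assert_array_equal(fit.V2, fit.V1 + fit.info_inverse)
        assert np.all(np.diag(fit.V2) > np.diag(fit.V1))
        se1, naive = fit.se("robust")[0], fit.se("naive")[0]
        assert fit.se("superpop")[0] == pytest.approx(
            np.sqrt(se1 ** 2 + naive ** 2))


class TestWaldCI:
    def test_level_95_multiplier(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        ci = wald_ci(fit, 0.95, "robust")
        half = (ci[:, 1] - ci[:, 0]) / 2.0
        np.testing.assert_allclose(half / fit.se("robust"), 1.96, atol=5e-3)

    def test_zero_variance_degenerate(self):
        fit = FitResult(beta=np.array([0.7]), names=("x",),
                        info_inverse=np.zeros((1, 1)), V1=np.zeros((1, 1)),
                        V2=np.zeros((1, 1)), loglik=0.0, score_norm=0.0,
                        iterations=0, converged=True)
        ci = wald_ci(fit, 0.95, "naive")
        assert ci[0, 0] == ci[0, 1] == 0.7

    def test_superpop_wider_than_robust(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        w1 = np.diff(wald_ci(fit, 0.95, "robust"), axis=1)
        w2 = np.diff(wald_ci(fit, 0.95, "superpop"), axis=1)
        assert np.all(w2 >= w1)

    def test_bad_level_rejected(self, rng):
        d = random_instance(rng)
        fit = fit_weighted_cox(d)
        with pytest.raises(ValueError):
            wald_ci(fit, 1.5)


def test_hazard_ratio_per_sd():
    assert round(hazard_ratio(1.39), 1) == 4.0
    assert round(hazard_ratio(0.05, 14.0), 1) == 2.0
    assert round(hazard_ratio(-0.11, 8.0), 1) == 0.4
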