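import numpy as np
import pytest

from ltcox import (
    Dataset,
    FitOptions,
    InvalidInputError,
    ParameterState,
    SubjectRecord,
    TimeGrid,
    fit,
    simulate_dataset,
)
from ltcox.data import build_time_grid
from ltcox.em import (
    beta_jacobian,
    estep_expectations,
    fd_beta_jacobian,
    newton_step_beta,
    score_beta,
    score_lambda,
    update_lambda,
)
from ltcox.likelihood import pairwise_loglik

from conftest import make_right_censored

INF = float("inf")


def truncated_poisson_mc(mu_vec, n_draws=1_000_000, seed=0):
    """Monte-Carlo means of independent Poisson counts conditioned on a
    positive total — the E-step's censored-interval distribution."""
    rng = np.random.default_rng(seed)
    W = rng.poisson(np.asarray(mu_vec), size=(n_draws, len(mu_vec)))
    keep = W.sum(axis=1) > 0
    return W[keep].mean(axis=0)


class TestEstep:
    def test_exact_event_unit_mass_at_event_time(self):
        ds = Dataset([SubjectRecord("a", 0.2, 1, (0.0,), T=0.9)])
        grid = TimeGrid(np.array([0.4, 0.9, 1.3]))
        ps = ParameterState([0.0], [0.2, 0.3, 0.1], grid)
        e = estep_expectations(ps, ds, grid)
        np.testing.assert_array_equal(e.values[0], [0.0, 1.0, 0.0])

    def test_right_censored_all_zero(self):
        ds = Dataset([SubjectRecord("a", 0.0, 0, (0.0,), L=0.9, R=INF)])
        grid = TimeGrid(np.array([0.4, 0.9, 1.3]))
        ps = ParameterState([0.0], [0.2, 0.3, 0.1], grid)
        e = estep_expectations(ps, ds, grid)
        np.testing.assert_array_equal(e.values[0], [0.0, 0.0, 0.0])

    def test_single_point_window_matches_analytic_and_mc(self):
        # one grid point in (L, R] with unit mass: mean of Poisson(1)
        # conditioned on being positive is 1/(1 - e^{-1})
        ds = Dataset([SubjectRecord("a", 0.0, 0, (0.0,), L=0.4, R=0.9)])
        grid = TimeGrid(np.array([0.4, 0.9]))
        ps = ParameterState([0.0], [0.3, 1.0], grid)
        e = estep_expectations(ps, ds, grid)
        analytic = 1.0 / (1.0 - np.exp(-1.0))
        assert e.values[0, 1] == pytest.approx(analytic, abs=1e-12)
        assert e.values[0, 0] == 0.0
        mc = truncated_poisson_mc([1.0])
        assert e.values[0, 1] == pytest.approx(mc[0], abs=0.01)

    def test_two_point_window_matches_mc_and_sums_above_one(self):
        ds = Dataset([SubjectRecord("a", 0.0, 0, (0.0,), L=0.2, R=1.0)])
        grid = TimeGrid(np.array([0.2, 0.5, 1.0]))
        ps = ParameterState([0.0], [0.4, 0.5, 0.5], grid)
        e = estep_expectations(ps, ds, grid)
        expected = 0.5 / (1.0 - np.exp(-1.0))
        assert e.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert e.values[0, 2] == pytest.approx(expected, abs=1e-12)
        assert e.values[0].sum() >= 1.0
        mc = truncated_poisson_mc([0.5, 0.5], seed=1)
        np.testing.assert_allclose(e.values[0, 1:], mc, atol=0.01)

    def test_three_point_uneven_window_matches_mc(self):
        ds = Dataset([SubjectRecord("a", 0.0, 0, (1.0,), L=0.1, R=1.2)])
        grid = TimeGrid(np.array([0.1, 0.3, 0.6, 1.2]))
        beta = np.array([0.5])
        lam = np.array([0.2, 0.3, 0.15, 0.6])
        ps = ParameterState(beta, lam, grid)
        e = estep_expectations(ps, ds, grid)
        mu = lam[1:] * np.exp(0.5)
        mc = truncated_poisson_mc(mu, seed=2)
        np.testing.assert_allclose(e.values[0, 1:], mc, atol=0.01)

    def test_left_censored_zero_at_entry_point(self):
        # L == A: the zero-constraint region is the entry point itself,
        # interval mass lives strictly after it
        ds = Dataset([SubjectRecord("a", 0.3, 0, (0.0,), L=0.3, R=0.9)])
        grid = TimeGrid(np.array([0.3, 0.6, 0.9]))
        ps = ParameterState([0.0], [0.2, 0.5, 0.5], grid)
        e = estep_expectations(ps, ds, grid)
        assert e.values[0, 0] == 0.0
        assert np.all(e.values[0, 1:] > 0)

    def test_values_vanish_outside_window(self, table1_design):
        ds = simulate_dataset(table1_design, 40, seed=2)
        grid = build_time_grid(ds, include_entry=False)
        ps = ParameterState([0.3, 0.3], np.full(grid.K, 1.0 / grid.K), grid)
        e = estep_expectations(ps, ds, grid)
        assert np.all(e.values[e.window == 0] == 0)

    def test_interval_without_grid_point_rejected(self):
        ds = Dataset([SubjectRecord("a", 0.0, 0, (0.0,), L=0.4, R=0.9)])
        grid = TimeGrid(np.array([0.2, 0.4]))  # nothing in (0.4, 0.9]
        ps = ParameterState([0.0], [0.3, 1.0], grid)
        with pytest.raises(InvalidInputError):
            estep_expectations(ps, ds, grid)


class TestLambdaUpdate:
    def test_events_over_atrisk_hand_value(self):
        # one exact event and one right-censored subject at the same grid
        # point, no covariate effect: the update is the classical
        # events / at-risk ratio 0.5; pairwise term vanishes (equal entry)
        ds = Dataset([
            SubjectRecord("a", 0.0, 1, (0.0,), T=1.0),
            SubjectRecord("b", 0.0, 0, (0.0,), L=1.0, R=INF),
        ])
        grid = build_time_grid(ds, include_entry=False)
        ps = ParameterState([0.0], [0.5], grid)
        e = estep_expectations(ps, ds, grid)
        for method in ("pairwise", "conditional"):
            lam, n_floored = update_lambda(e, ps, ds, grid, method)
            assert lam[0] == pytest.approx(0.5, abs=1e-14)
            assert n_floored == 0

    def test_equal_entry_times_make_methods_coincide(self, table1_design):
        ds = simulate_dataset(table1_design, 30, seed=4).with_zero_entry()
        grid = build_time_grid(ds, include_entry=False)
        ps = ParameterState([0.4, -0.2], np.full(grid.K, 1.0 / grid.K), grid)
        e = estep_expectations(ps, ds, grid)
        lam_p, _ = update_lambda(e, ps, ds, grid, "pairwise")
        lam_c, _ = update_lambda(e, ps, ds, grid, "conditional")
        np.testing.assert_allclose(lam_p, lam_c, atol=1e-14)

    def test_zero_numerator_estimates_zero(self):
        # a grid point receiving no expected counts keeps a zero jump
        ds = Dataset([
            SubjectRecord("a", 0.0, 1, (0.0,), T=1.0),
            SubjectRecord("b", 0.0, 0, (0.0,), L=0.5, R=INF),
        ])
        grid = build_time_grid(ds, include_entry=False)  # (0.5, 1.0)
        ps = ParameterState([0.0], [0.3, 0.3], grid)
        e = estep_expectations(ps, ds, grid)
        lam, _ = update_lambda(e, ps, ds, grid, "conditional")
        assert lam[grid.points == 0.5][0] == 0.0
        assert lam[grid.points == 1.0][0] > 0


class TestBetaStep:
    def _fixture(self, n=8, seed=3):
        design_ds = make_right_censored(n, seed, p=2)
        grid = build_time_grid(design_ds, include_entry=False)
        ps = ParameterState([0.3, -0.2], np.full(grid.K, 1.0 / grid.K), grid)
        return design_ds, grid, ps

    def test_zero_covariates_give_zero_score(self):
        recs = [SubjectRecord(i, 0.1 * i, 1, (0.0,), T=1.0 + 0.1 * i)
                for i in range(5)]
        ds = Dataset(recs)
        grid = build_time_grid(ds, include_entry=False)
        ps = ParameterState([0.7], np.full(grid.K, 0.2), grid)
        e = estep_expectations(ps, ds, grid)
        u = score_beta(ps, e, ds, grid, "pairwise")
        np.testing.assert_allclose(u, 0.0, atol=1e-14)

    def test_score_matches_finite_difference_of_surrogate(self):
        # U_beta must be the beta-gradient of the E-step surrogate
        # objective with expectations held fixed
        ds, grid, ps = self._fixture()
        e = estep_expectations(ps, ds, grid)
        n = ds.n
        Z = ds.covariates()
        win = e.window

        def surrogate(beta):
            g = np.exp(Z @ beta)
            lg = np.log(ps.lam[None, :] * g[:, None],
                        where=ps.lam[None, :] > 0,
                        out=np.zeros((n, grid.K)))
            term = win * (e.values * lg - ps.lam[None, :] * g[:, None])
            ps_b = ParameterState(beta, ps.lam, grid)
            return term.sum() / n + pairwise_loglik(ps_b, ds) / (n * (n - 1))

        u = score_beta(ps, e, ds, grid, "pairwise")
        h = 1e-6
        for k in range(2):
            step = np.zeros(2)
            step[k] = h
            fd = (surrogate(ps.beta + step) - surrogate(ps.beta - step)) / (2 * h)
            assert u[k] == pytest.approx(fd, abs=1e-6)

    def test_equal_entry_times_drop_pairwise_score_term(self):
        ds, grid, _ = self._fixture()
        ds0 = ds.with_zero_entry()
        grid0 = build_time_grid(ds0, include_entry=False)
        ps = ParameterState([0.3, -0.2], np.full(grid0.K, 1.0 / grid0.K), grid0)
        e = estep_expectations(ps, ds0, grid0)
        u_p = score_beta(ps, e, ds0, grid0, "pairwise")
        u_c = score_beta(ps, e, ds0, grid0, "conditional")
        np.testing.assert_allclose(u_p, u_c, atol=1e-14)

    def test_analytic_jacobian_matches_central_differences(self, table1_design):
        ds = simulate_dataset(table1_design, 25, seed=6)
        grid = build_time_grid(ds, include_entry=False)
        ps = ParameterState([0.4, 0.1], np.full(grid.K, 1.0 / grid.K), grid)
        e = estep_expectations(ps, ds, grid)
        for method in ("pairwise", "conditional"):
            J = beta_jacobian(ps, e, ds, grid, method)
            J_fd = fd_beta_jacobian(ps, e, ds, grid, method)
            np.testing.assert_allclose(J, J_fd, atol=1e-6)

    def test_newton_fixed_point_leaves_beta_unchanged(self):
        # at a deeply converged fit the score is ~0, so one more Newton
        # step must not move beta
        ds = make_right_censored(40, seed=9, p=1)
        res = fit(ds, FitOptions(method="pairwise", tol=1e-12,
                                 max_iter=5000, track_objective=False))
        ps = res.params
        e = estep_expectations(ps, ds, res.grid)
        new_beta, fell_back = newton_step_beta(ps, e, ds, res.grid, "pairwise")
        assert not fell_back
        np.testing.assert_allclose(new_beta, ps.beta, atol=1e-8)

    def test_step_ascends_when_jacobian_negative_definite(self):
        ds, grid, ps = self._fixture(n=12, seed=5)
        e = estep_expectations(ps, ds, grid)
        u = score_beta(ps, e, ds, grid, "pairwise")
        J = beta_jacobian(ps, e, ds, grid, "pairwise")
        assert np.all(np.linalg.eigvalsh(J) < 0)
        new_beta, _ = newton_step_beta(ps, e, ds, grid, "pairwise")
        assert (new_beta - ps.beta) @ u > 0


class TestFixedPoint:
    def test_scores_vanish_at_converged_estimate(self):
        # the closed-form jump update is the solution of its own score
        # equation, so at the EM limit both composite scores vanish
        ds = make_right_censored(50, seed=11, p=2)
        res = fit(ds, FitOptions(method="pairwise", tol=1e-12,
                                 max_iter=8000, track_objective=False))
        assert res.converged
        ps = res.params
        e = estep_expectations(ps, ds, res.grid)
        u_lam = score_lambda(ps, e, ds, res.grid, "pairwise")
        active = ps.lam > 1e-9
        np.testing.assert_allclose(u_lam[active], 0.0, atol=1e-6)
        u_beta = score_beta(ps, e, ds, res.grid, "pairwise")
        np.testing.assert_allclose(u_beta, 0.0, atol=1e-6)

    def test_em_limit_matches_bisection_root_of_profiled_score(self):
        # independent solver: profile the jumps by iterating the
        # closed-form update at fixed beta, then bisect U_beta in beta
        ds = make_right_censored(10, seed=13, p=1)
        grid = build_time_grid(ds, include_entry=False)

        def profiled_score(beta_val):
            beta = np.array([beta_val])
            lam = np.full(grid.K, 1.0 / grid.K)
            for _ in range(4000):
                ps = ParameterState(beta, lam, grid)
                e = estep_expectations(ps, ds, grid)
                new_lam, _ = update_lambda(e, ps, ds, grid, "pairwise")
                if np.abs(new_lam - lam).sum() < 1e-12:
                    lam = new_lam
                    break
                lam = new_lam
            ps = ParameterState(beta, lam, grid)
            e = estep_expectations(ps, ds, grid)
            return score_beta(ps, e, ds, grid, "pairwise")[0]

        lo, hi = -2.0, 3.0
        assert profiled_score(lo) > 0 > profiled_score(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if profiled_score(mid) > 0:
                lo = mid
            else:
                hi = mid
        root = 0.5 * (lo + hi)

        res = fit(ds, FitOptions(method="pairwise", tol=1e-10, max_iter=20000,
                                 track_objective=False))
        assert res.beta_hat[0] == pytest.approx(root, abs=1e-4)


class TestFitContracts:
    def test_zero_entry_makes_pairwise_and_conditional_identical(
            self, table1_design):
        ds = simulate_dataset(table1_design, 40, seed=21).with_zero_entry()
        rp = fit(ds, FitOptions(method="pairwise", track_objective=False))
        rc = fit(ds, FitOptions(method="conditional", track_objective=False))
        np.testing.assert_allclose(rp.beta_hat, rc.beta_hat, atol=1e-8)
        np.testing.assert_allclose(rp.lam_hat, rc.lam_hat, atol=1e-8)

    def test_ignore_truncation_equals_conditional_on_zeroed_entries(
            self, table1_design):
        ds = simulate_dataset(table1_design, 40, seed=22)
        ri = fit(ds, FitOptions(method="ignore_truncation",
                                track_objective=False))
        rc = fit(ds.with_zero_entry(), FitOptions(method="conditional",
                                                  track_objective=False))
        np.testing.assert_array_equal(ri.beta_hat, rc.beta_hat)
        np.testing.assert_array_equal(ri.lam_hat, rc.lam_hat)

    def test_iteration_cap_reports_nonconvergence_without_raising(
            self, small_pic_dataset):
        res = fit(small_pic_dataset, FitOptions(method="pairwise", max_iter=3,
                                                track_objective=False))
        assert not res.converged
        assert res.n_iter == 3
        assert any("did not converge" in w for w in res.warnings)

    def test_nonnegative_jumps_and_no_floor_activations(self, table1_design):
        ds = simulate_dataset(table1_design, 60, seed=23)
        res = fit(ds, FitOptions(method="pairwise", track_objective=False,
                                 max_iter=3000))
        assert np.all(res.lam_hat >= 0)
        assert res.n_floored == 0

    def test_invalid_method_rejected(self):
        with pytest.raises(InvalidInputError):
            FitOptions(method="marginal")
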