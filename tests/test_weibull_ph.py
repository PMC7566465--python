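"""Likelihood, MLE, hazard ratios and AIC for the Weibull PH model."""

import numpy as np
import pytest
from scipy.integrate import quad

import pmfstate as pm
from pmfstate.weibull_ph import FitError


def row(t0, t1, status, cov=None, k=1):
    return pm.TransitionRow("s", k, t0, t1, status, cov or {})


def sim_survival_rows(n, shape, scale, beta, censor_at, seed):
    """Single-transition cohort: Weibull PH event times, fixed censoring."""
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < 0.5).astype(float)
    E = rng.exponential(size=n)
    t = (E / (scale * np.exp(beta * x))) ** (1.0 / shape)
    obs = np.minimum(t, censor_at)
    return [
        pm.TransitionRow(str(i), 1, 0.0, float(obs[i]), int(t[i] <= censor_at),
                         {"x": float(x[i])})
        for i in range(n)
    ]


class TestLogLikelihood:
    def test_exponential_closed_form(self):
        """shape=1, scale=0.1, one event at t=2: log(0.1) - 0.2."""
        ll = pm.transition_log_likelihood([np.log(0.1), 0.0], [row(0.0, 2.0, 1)])
        assert ll == pytest.approx(np.log(0.1) - 0.2, abs=1e-12)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            pm.transition_log_likelihood([0.0, 0.0], [row(2.0, 2.0, 1)])

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            pm.transition_log_likelihood([np.nan, 0.0], [row(0.0, 1.0, 1)])

    def test_matches_quadrature_oracle(self):
        """Cumulative-hazard terms agree with numerical integration of the
        hazard to 1e-8 on random small datasets."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            log_lam, log_gam = rng.normal(scale=0.5, size=2)
            beta = rng.normal(scale=0.3)
            rows = []
            for i in range(8):
                t0 = rng.uniform(0, 2)
                t1 = t0 + rng.uniform(0.1, 3)
                rows.append(row(t0, t1, int(rng.uniform() < 0.5),
                                {"x": float(rng.integers(2))}))
            lam, gam = np.exp(log_lam), np.exp(log_gam)
            expected = 0.0
            for r in rows:
                rate = np.exp(beta * r.covariates["x"])
                h = lambda t: lam * gam * t ** (gam - 1.0) * rate
                H, _ = quad(h, r.t_start, r.t_stop)
                if r.status:
                    expected += np.log(h(r.t_stop))
                expected -= H
            got = pm.transition_log_likelihood(
                [log_lam, log_gam, beta], rows, ["x"]
            )
            assert got == pytest.approx(expected, abs=1e-8)


class TestFit:
    def test_exponential_mle_closed_form(self):
        """With shape fixed at 1, scale-hat = events / exposure exactly."""
        rows = [row(0.0, 2.0, 1), row(1.0, 4.0, 0), row(0.5, 3.0, 1)]
        fit = pm.fit_transition(rows, [], fix_shape=1.0)
        events = 2
        exposure = 2.0 + 3.0 + 2.5
        assert fit.scale == pytest.approx(events / exposure, rel=1e-8)
        assert fit.shape == 1.0

    def test_matches_grid_search_oracle(self):
        """MLE agrees with an independent nested grid search on a 20-row
        toy dataset to 1e-4 in every parameter."""
        rows = sim_survival_rows(20, 1.4, 0.2, 0.7, 6.0, seed=5)
        fit = pm.fit_transition(rows, ["x"])

        def nll(theta):
            return -pm.transition_log_likelihood(theta, rows, ["x"])

        center = np.array([np.log(0.2), np.log(1.4), 0.7])
        width = np.array([1.5, 1.0, 1.5])
        for _ in range(12):  # nested grid refinement, 9 points per axis
            axes = [np.linspace(c - w, c + w, 9) for c, w in zip(center, width)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            vals = [nll(g) for g in grid]
            center = grid[int(np.argmin(vals))]
            width *= 0.28
        assert np.log(fit.scale) == pytest.approx(center[0], abs=1e-4)
        assert np.log(fit.shape) == pytest.approx(center[1], abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(center[2], abs=1e-4)

    def test_matches_lifelines_on_right_censored_data(self):
        """Independent cross-check: lifelines' Weibull AFT fit maps onto the
        PH parametrization (beta_PH = -shape * beta_AFT)."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rows = sim_survival_rows(400, 1.3, 0.1, 0.6, 10.0, seed=9)
        fit = pm.fit_transition(rows, ["x"])
        df = pd.DataFrame(
            {
                "T": [r.t_stop for r in rows],
                "E": [r.status for r in rows],
                "x": [r.covariates["x"] for r in rows],
            }
        )
        aft = lifelines.WeibullAFTFitter().fit(df, "T", "E")
        rho = np.exp(aft.params_["rho_"]["Intercept"])
        lam0 = np.exp(aft.params_["lambda_"]["Intercept"])
        b_x = aft.params_["lambda_"]["x"]
        assert fit.shape == pytest.approx(rho, rel=1e-4)
        assert fit.scale == pytest.approx(lam0 ** (-rho), rel=1e-3)
        assert fit.coefficients["x"] == pytest.approx(-rho * b_x, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(aft.log_likelihood_, rel=1e-9)

    def test_parameter_recovery_large_n(self):
        """True log-HR (ln 6.53) recovered within 3 Wald SEs at n=5000."""
        true_beta = np.log(6.53)
        rows = sim_survival_rows(5000, 1.3, 0.05, true_beta, 8.0, seed=17)
        fit = pm.fit_transition(rows, ["x"])
        se = np.sqrt(fit.covariance[2, 2])
        assert abs(fit.coefficients["x"] - true_beta) < 3 * se
        assert abs(fit.shape - 1.3) / 1.3 < 0.1

    def test_score_vanishes_at_optimum(self):
        rows = sim_survival_rows(200, 0.8, 0.15, -0.4, 12.0, seed=3)
        fit = pm.fit_transition(rows, ["x"])
        theta = fit.params
        eps = 1e-6
        for j in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            g = (
                pm.transition_log_likelihood(tp, rows, ["x"])
                - pm.transition_log_likelihood(tm, rows, ["x"])
            ) / (2 * eps)
            assert abs(g) < 1e-4

    def test_time_rescaling_invariance(self):
        """Years -> months rescales scale-hat by c**-shape and leaves
        shape, beta and the likelihood shape intact."""
        rows = sim_survival_rows(300, 1.2, 0.1, 0.5, 9.0, seed=21)
        c = 12.0
        rows_m = [
            pm.TransitionRow(r.subject_id, r.transition, r.t_start * c,
                             r.t_stop * c, r.status, r.covariates)
            for r in rows
        ]
        f_y = pm.fit_transition(rows, ["x"])
        f_m = pm.fit_transition(rows_m, ["x"])
        assert f_m.shape == pytest.approx(f_y.shape, rel=1e-5)
        assert f_m.coefficients["x"] == pytest.approx(
            f_y.coefficients["x"], abs=1e-5
        )
        assert f_m.scale == pytest.approx(f_y.scale * c**-f_y.shape, rel=1e-4)
        # log-likelihoods differ by the Jacobian of the time change
        n_events = f_y.n_events
        assert f_m.log_likelihood == pytest.approx(
            f_y.log_likelihood - n_events * np.log(c), rel=1e-9
        )

    def test_adding_covariates_never_decreases_loglik(self):
        rng = np.random.default_rng(33)
        rows = sim_survival_rows(150, 1.1, 0.2, 0.4, 7.0, seed=8)
        rows = [
            pm.TransitionRow(r.subject_id, 1, r.t_start, r.t_stop, r.status,
                             {**r.covariates, "noise": float(rng.integers(2))})
            for r in rows
        ]
        ll0 = pm.fit_transition(rows, ["x"]).log_likelihood
        ll1 = pm.fit_transition(rows, ["x", "noise"]).log_likelihood
        assert ll1 >= ll0 - 1e-8

    def test_zero_events_is_error(self):
        rows = [row(0.0, 1.0, 0), row(0.0, 2.0, 0)]
        with pytest.raises(FitError, match="no events"):
            pm.fit_transition(rows, [])

    def test_rank_deficient_design_is_error(self):
        rows = [row(0.0, t, s, {"a": 1.0, "b": 1.0})
                for t, s in [(1.0, 1), (2.0, 0), (3.0, 1)]]
        with pytest.raises(FitError, match="rank"):
            pm.fit_transition(rows, ["a", "b"])


class TestInference:
    def _fit_with(self, betas, ses):
        cov = np.zeros((2 + len(betas), 2 + len(betas)))
        for j, se in enumerate(ses):
            cov[2 + j, 2 + j] = se**2
        return pm.WeibullPHFit(1, 1.0, 0.1, dict(betas), cov, -100.0, 10, 20)

    def test_null_effect(self):
        fit = self._fit_with({"x": 0.0}, [0.5])
        tab = pm.hazard_ratios(fit)
        assert tab.HR[0] == 1.0
        assert tab.CI_low[0] == pytest.approx(np.exp(-1.959964 * 0.5), rel=1e-5)
        assert tab.CI_high[0] == pytest.approx(np.exp(1.959964 * 0.5), rel=1e-5)
        assert tab.p[0] == pytest.approx(1.0)

    def test_degenerate_ci_in_zero_se_limit(self):
        fit = self._fit_with({"x": np.log(2.0)}, [0.0])
        tab = pm.hazard_ratios(fit)
        assert tab.HR[0] == pytest.approx(2.0)
        assert tab.CI_low[0] == pytest.approx(2.0)
        assert tab.CI_high[0] == pytest.approx(2.0)

    def test_missing_covariance_is_error(self):
        fit = pm.WeibullPHFit(1, 1.0, 0.1, {"x": 0.0}, None, -1.0, 1, 2)
        with pytest.raises(FitError, match="covariance"):
            pm.hazard_ratios(fit)


class TestAIC:
    def test_arithmetic(self):
        fit = pm.WeibullPHFit(1, 1.0, 0.1, {}, None, -100.0, 5, 10)
        assert pm.aic(fit) == 204.0

    def test_nested_model_difference_identity(self):
        """AIC difference between nested fits is -2*delta(logL) + 2*delta(k)."""
        rows = sim_survival_rows(120, 1.0, 0.3, 0.5, 5.0, seed=2)
        f0 = pm.fit_transition(rows, [])
        f1 = pm.fit_transition(rows, ["x"])
        lr = -2.0 * (f0.log_likelihood - f1.log_likelihood)
        assert pm.aic(f1) - pm.aic(f0) == pytest.approx(2.0 - lr, abs=1e-9)
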