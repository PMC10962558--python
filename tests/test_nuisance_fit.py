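import warnings

import numpy as np
import pytest

from permcrt.nuisance_fit import (
    FitError,
    build_cluster_covariance,
    fit_univariate_nuisance,
    link_weights,
    null_marginal_means,
)
from permcrt.synthetic_trials import SimulationScenario, simulate_scenario
from permcrt.trial_data import OutcomeSpec

from conftest import known_mean_fit, make_trial


def _fit_quiet(data, spec, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_univariate_nuisance(data, spec, **kw)


class TestGaussianFit:
    def test_zero_cluster_variance_reduces_to_ols(self):
        rng = np.random.default_rng(11)
        n, C = 10, 8
        clusters = np.repeat(np.arange(C), n)
        treat = (clusters < C // 2).astype(int)
        eps = rng.normal(0, 1, C * n)
        # remove cluster-mean noise so all clusters share one mean exactly
        eps -= np.array([eps[clusters == c].mean() for c in range(C)])[clusters]
        y = 1.0 + eps
        d = make_trial(y, clusters, treat)
        fit = _fit_quiet(d, OutcomeSpec("y", "gaussian"))
        ols_diff = y[treat == 1].mean() - y[treat == 0].mean()
        assert fit.theta_hat["tau2"] == pytest.approx(0.0, abs=1e-4)
        assert fit.delta_hat == pytest.approx(ols_diff, abs=1e-6)

    def test_parameter_recovery_on_bivariate_gaussian_dgp(self):
        """Estimator bias for delta, sigma^2, tau^2 within 3 MC SEs of zero.

        Restricted ML is used for the variance-component bias check (plain ML
        variance components carry the well-known downward finite-sample bias).
        """
        sc = SimulationScenario(model_id=1, clusters_per_arm=14)
        spec = sc.outcome_specs[0]
        n_rep = 200
        deltas, sig2, tau2 = [], [], []
        for r in range(n_rep):
            d = simulate_scenario(sc, replicate_seed=1000 + r)
            f = _fit_quiet(d, spec, reml=True)
            deltas.append(f.delta_hat)
            sig2.append(f.theta_hat["sigma2"])
            tau2.append(f.theta_hat["tau2"])
        for vals, truth in ((deltas, 0.0), (sig2, 1.0), (tau2, 0.05)):
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - truth) < 3 * se + 1e-3

    def test_mean_icc_near_nominal_under_ml(self):
        sc = SimulationScenario(model_id=1, clusters_per_arm=14)
        spec = sc.outcome_specs[0]
        iccs = []
        for r in range(150):
            d = simulate_scenario(sc, replicate_seed=5000 + r)
            f = _fit_quiet(d, spec)
            th = f.theta_hat
            iccs.append(th["tau2"] / (th["tau2"] + th["sigma2"]))
        assert np.mean(iccs) == pytest.approx(0.05, abs=0.015)


class TestNonGaussianFit:
    def test_poisson_laplace_matches_lme4_reference(self, model2_data, model2_fits):
        # reference values from lme4 (Laplace) on the identical dataset
        # (replicate seed 42): glmer(y1 ~ treatment + (1|cluster)) for the
        # free treatment effect, glmer(y1 ~ 1 + (1|cluster)) for the
        # null-constrained nuisance
        fit = model2_fits[0]
        assert fit.spec.family == "poisson"
        assert fit.delta_hat == pytest.approx(-0.1263496, abs=5e-4)
        assert fit.se_hat == pytest.approx(0.08897086, rel=5e-3)
        assert fit.mu0_hat == pytest.approx(0.9548314, abs=5e-4)
        assert fit.theta_hat["tau2"] == pytest.approx(0.01232363, abs=5e-4)

    def test_gaussian_ml_matches_lme4_reference(self, model2_fits):
        # lme4::lmer(y2 ~ treatment + (1|cluster), REML=FALSE) and the
        # intercept-only null model, same data
        fit = model2_fits[1]
        assert fit.delta_hat == pytest.approx(0.1714017, abs=1e-5)
        assert fit.se_hat == pytest.approx(0.12284859, rel=1e-3)
        assert fit.mu0_hat == pytest.approx(1.102264, abs=1e-5)
        assert fit.theta_hat["tau2"] == pytest.approx(0.01114014, abs=1e-5)
        assert fit.theta_hat["sigma2"] == pytest.approx(0.9805147, abs=1e-5)

    def test_adaptive_quadrature_agrees_with_laplace(self, model2_data):
        spec = SimulationScenario(model_id=2).outcome_specs[0]
        lap = _fit_quiet(model2_data, spec, nagq=1)
        agq = _fit_quiet(model2_data, spec, nagq=15)
        assert agq.delta_hat == pytest.approx(lap.delta_hat, abs=2e-3)
        assert agq.theta_hat["tau2"] == pytest.approx(lap.theta_hat["tau2"], abs=2e-3)

    def test_constant_poisson_outcome_fails_loudly(self):
        d = make_trial(np.zeros(8), clusters=[1, 1, 2, 2, 3, 3, 4, 4],
                       treatment=[1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(FitError, match="degenerate"):
            fit_univariate_nuisance(d, OutcomeSpec("y", "poisson"))

    def test_fixed_effects_fallback_by_request(self, model2_data):
        spec = SimulationScenario(model_id=2).outcome_specs[0]
        fit = _fit_quiet(model2_data, spec, random_effects=False,
                         theta={"tau2": 0.05})
        assert not fit.used_random_effects
        assert fit.theta_hat["tau2"] == 0.05


class TestNullMarginalMeans:
    def test_identity_link_constant_predictor(self):
        d = make_trial([0.0, 0.0], clusters=[1, 2], treatment=[0, 1])
        fit = known_mean_fit(d, mu0=1.0)
        np.testing.assert_allclose(null_marginal_means(fit, d, 0.0), [1.0, 1.0])

    def test_log_link_direct_formula(self):
        d = make_trial([0.0, 0.0], clusters=[1, 2], treatment=[0, 1])
        fit = known_mean_fit(d, mu0=1.0, family="poisson")
        mu = null_marginal_means(fit, d, 0.5)
        assert mu[0] == pytest.approx(np.exp(1.0))
        assert mu[1] == pytest.approx(np.exp(1.5))

    def test_delta_star_moves_only_treated_rows(self, model2_data, model2_fits):
        fit = model2_fits[1]
        m0 = null_marginal_means(fit, model2_data, 0.0)
        m1 = null_marginal_means(fit, model2_data, 0.7)
        treated = model2_data.treatment == 1
        np.testing.assert_allclose(m0[~treated], m1[~treated])
        assert np.all(m1[treated] != m0[treated])

    def test_nonfinite_delta_star_rejected(self, model2_data, model2_fits):
        with pytest.raises(ValueError):
            null_marginal_means(model2_fits[0], model2_data, np.nan)


class TestClusterCovariance:
    def test_exchangeable_entries(self):
        d = make_trial(np.zeros(3), clusters=[1, 1, 1], treatment=[1, 1, 1])
        fit = known_mean_fit(d, theta={"sigma2": 1.0, "tau2": 0.05})
        cov = build_cluster_covariance(fit, d)
        V = cov.V[0]
        np.testing.assert_allclose(np.diag(V), [1.05] * 3)
        off = V[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.05)

    def test_zero_tau_gives_scaled_identity(self):
        d = make_trial(np.zeros(4), clusters=[1] * 4, treatment=[1] * 4)
        fit = known_mean_fit(d, theta={"sigma2": 2.0, "tau2": 0.0})
        cov = build_cluster_covariance(fit, d)
        np.testing.assert_allclose(cov.V[0], 2.0 * np.eye(4))

    def test_inverse_contract(self, model2_data, model2_fits):
        for fit in model2_fits:
            cov = build_cluster_covariance(fit, model2_data)
            for V, Vinv in zip(cov.V, cov.Vinv):
                err = np.max(np.abs(V @ Vinv - np.eye(len(V))))
                assert err < 1e-8

    def test_ar_decay_structure(self):
        d = make_trial(
            np.zeros(4), clusters=[1, 1, 1, 1], treatment=[0, 0, 1, 1],
            period=[1, 1, 2, 2],
        )
        fit = known_mean_fit(d, theta={"sigma2": 1.0, "tau2": 1.0, "lam": 0.7})
        cov = build_cluster_covariance(fit, d)
        V = cov.V[0]
        assert V[0, 1] == pytest.approx(1.0)       # same period
        assert V[0, 2] == pytest.approx(0.7)       # adjacent periods
        assert V[0, 0] == pytest.approx(2.0)       # sigma^2 + tau^2

    @pytest.mark.parametrize("link,expected", [
        ("identity", 1.0),
        ("log", 1.0 / 2.0),
        ("logit", 1.0 / (0.25 * 0.75)),
    ])
    def test_link_weights(self, link, expected):
        mu = np.array([2.0]) if link == "log" else np.array([0.25] if link == "logit" else [3.0])
        if link == "identity":
            assert link_weights(link, mu)[0] == 1.0
        else:
            assert link_weights(link, mu)[0] == pytest.approx(expected)
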