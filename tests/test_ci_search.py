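import warnings

import numpy as np
import pytest
from scipy import stats

from permcrt.ci_search import (
    convergence_diagnostic,
    search_confidence_set,
    step_constant,
    update_bound,
)
from permcrt.nuisance_fit import fit_univariate_nuisance
from permcrt.permutation_engine import PermutationPlan, permutation_statistic_matrix
from permcrt.synthetic_trials import SimulationScenario, simulate_scenario


@pytest.fixture(scope="module")
def gaussian_trial():
    """One bivariate-Gaussian replicate with a fitted single-outcome model."""
    sc = SimulationScenario(model_id=1)
    d = simulate_scenario(sc, 11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_univariate_nuisance(d, sc.outcome_specs[1])
    return d, fit


def grid_inversion_interval(d, fit, alpha=0.05, half_width_se=4.0, n_grid=201):
    """Oracle: test a fine grid of null values by full enumeration of the
    allocation group and take sup/inf of the non-rejected set."""
    plan = PermutationPlan(scheme="parallel_1to1", enumerate_all=True)
    grid = np.linspace(fit.delta_hat - half_width_se * fit.se_hat,
                       fit.delta_hat + half_width_se * fit.se_hat, n_grid)
    ps = np.array([
        permutation_statistic_matrix(d, [fit], [None], [g], plan).p_raw[0]
        for g in grid
    ])
    keep = grid[ps > alpha]
    return keep.min(), keep.max()


class TestStepConstant:
    def test_value_at_alpha_005(self):
        assert step_constant(0.05) == pytest.approx(0.3392, abs=5e-4)

    def test_value_at_alpha_05_is_zero(self):
        assert step_constant(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_formula_on_grid(self):
        # independent evaluation of 2 z phi(z) at z = Phi^-1(1 - a)
        for a in (0.01, 0.025, 0.1, 0.2):
            z = stats.norm.ppf(1 - a)
            expected = 2.0 * z * stats.norm.pdf(z)
            assert step_constant(a) == pytest.approx(expected, rel=1e-12)
            assert step_constant(a) > 0.0

    def test_boundary_rejected(self):
        for a in (0.0, 1.0):
            with pytest.raises(ValueError):
                step_constant(a)


class TestUpdateBound:
    def test_upper_rejected(self):
        assert update_bound(1.0, 0.3, 0.05, 4, True, "upper") == pytest.approx(0.99625)

    def test_upper_not_rejected(self):
        assert update_bound(1.0, 0.3, 0.05, 4, False, "upper") == pytest.approx(1.07125)

    def test_lower_mirrors_upper(self):
        up_r = update_bound(1.0, 0.3, 0.05, 4, True, "upper") - 1.0
        lo_r = update_bound(1.0, 0.3, 0.05, 4, True, "lower") - 1.0
        assert lo_r == pytest.approx(-up_r)
        up_n = update_bound(1.0, 0.3, 0.05, 4, False, "upper") - 1.0
        lo_n = update_bound(1.0, 0.3, 0.05, 4, False, "lower") - 1.0
        assert lo_n == pytest.approx(-up_n)

    def test_step_decay_sums_to_convergence(self):
        """With a fixed rejection probability of 1 - alpha*, the recursion is
        a Robbins-Monro process whose iterates settle (synthetic Bernoulli
        rejection oracle with known quantile)."""
        rng = np.random.default_rng(0)
        alpha = 0.05
        b = 2.0
        for q in range(1, 20_001):
            rejected = rng.random() < (1 - alpha)
            b = update_bound(b, 0.4, alpha, q, rejected, "upper")
        assert abs(b - 2.0) < 0.5  # bounded walk, no drift to infinity
        # and late iterates move by O(1/q)
        assert abs(update_bound(b, 0.4, alpha, 20_000, True, "upper") - b) < 1e-4

    def test_invalid_iteration(self):
        with pytest.raises(ValueError):
            update_bound(1.0, 0.3, 0.05, 0, True)


class TestSearch:
    def test_trace_contract(self, gaussian_trial):
        d, fit = gaussian_trial
        Q = 200
        cs = search_confidence_set(d, [fit], method="none", Q=Q, seed=3,
                                   scheme="parallel_1to1")
        assert cs.trace.shape == (Q, 1, 2)
        assert cs.trace[0, 0, 1] == pytest.approx(fit.delta_hat + 2 * fit.se_hat)
        assert cs.trace[0, 0, 0] == pytest.approx(fit.delta_hat - 2 * fit.se_hat)
        assert cs.lower[0] < fit.delta_hat < cs.upper[0]

    def test_short_search_warns(self, gaussian_trial):
        d, fit = gaussian_trial
        with pytest.warns(UserWarning, match="unreliable"):
            search_confidence_set(d, [fit], method="none", Q=50, seed=3,
                                  scheme="parallel_1to1")

    def test_matches_grid_inversion_oracle(self, gaussian_trial):
        """Single-parameter, no correction: the searched limits sit near the
        sup/inf of non-rejected null values from exhaustive test inversion.
        Started at the oracle limits (equilibrium check) agreement is tight;
        from the default 2-SE start the slow 1/q transient leaves a drift of
        a fraction of one standard error."""
        d, fit = gaussian_trial
        lo, up = grid_inversion_interval(d, fit)
        cs_eq = search_confidence_set(
            d, [fit], method="none", Q=10_000, seed=5, scheme="parallel_1to1",
            start=(np.array([lo]), np.array([up])),
        )
        assert cs_eq.lower[0] == pytest.approx(lo, abs=0.15 * fit.se_hat)
        assert cs_eq.upper[0] == pytest.approx(up, abs=0.15 * fit.se_hat)

        cs = search_confidence_set(d, [fit], method="none", Q=10_000, seed=5,
                                   scheme="parallel_1to1")
        assert cs.lower[0] == pytest.approx(lo, abs=0.5 * fit.se_hat)
        assert cs.upper[0] == pytest.approx(up, abs=0.5 * fit.se_hat)

    def test_seed_stability(self, gaussian_trial):
        d, fit = gaussian_trial
        a = search_confidence_set(d, [fit], method="none", Q=4000, seed=1,
                                  scheme="parallel_1to1")
        b = search_confidence_set(d, [fit], method="none", Q=4000, seed=2,
                                  scheme="parallel_1to1")
        width = a.widths[0]
        assert abs(a.upper[0] - b.upper[0]) < 0.1 * width
        assert abs(a.lower[0] - b.lower[0]) < 0.1 * width

    def test_methods_nest_for_two_outcomes(self):
        """Bonferroni sets should not be narrower than Romano-Wolf sets on
        the same data and seeds (efficiency ordering, up to search noise)."""
        sc = SimulationScenario(model_id=2)
        d = simulate_scenario(sc, 21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = [fit_univariate_nuisance(d, s) for s in sc.outcome_specs]
        widths = {}
        for method in ("romano_wolf", "holm", "bonferroni"):
            cs = search_confidence_set(d, fits, method=method, Q=3000, seed=13,
                                       scheme="parallel_1to1")
            widths[method] = cs.widths.sum()
        slack = 0.1 * widths["romano_wolf"]
        assert widths["romano_wolf"] <= widths["holm"] + slack
        assert widths["holm"] <= widths["bonferroni"] + slack


class TestConvergenceDiagnostic:
    def _trace(self, upper_series, lower_series):
        Q = len(upper_series)
        t = np.empty((Q, 1, 2))
        t[:, 0, 0] = lower_series
        t[:, 0, 1] = upper_series
        return t

    def test_constant_tail_converged(self):
        t = self._trace(np.ones(500), -np.ones(500))
        conv, _ = convergence_diagnostic(t)
        assert conv.all()

    def test_monotone_ramp_not_converged(self):
        ramp = np.linspace(0.0, 3.0, 500)
        t = self._trace(1.0 + ramp, -1.0 - ramp)
        conv, drift = convergence_diagnostic(t)
        assert not conv.any()
        assert drift[0, 1] > 0

    def test_trace_frame_and_plot(self, gaussian_trial, tmp_path):
        d, fit = gaussian_trial
        cs = search_confidence_set(d, [fit], method="none", Q=150, seed=3,
                                   scheme="parallel_1to1")
        frame = cs.trace_frame()
        assert set(frame.columns) == {"iteration", "outcome", "side", "value"}
        assert len(frame) == 2 * 150
        out = tmp_path / "trace.png"
        cs.plot_trace(out)
        assert out.exists()
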