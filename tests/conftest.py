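import numpy as np
import pandas as pd
import pytest

from permcrt.trial_data import ClusterTrialData, OutcomeSpec
from permcrt.nuisance_fit import NuisanceFit
from permcrt.synthetic_trials import SimulationScenario, simulate_scenario


def make_trial(y, clusters, treatment, period=None, outcome="y", extra=None):
    """Small ClusterTrialData from raw arrays (single outcome)."""
    df = pd.DataFrame({
        "cluster": clusters,
        "treatment": treatment,
        outcome: np.asarray(y, float),
    })
    if period is not None:
        df["period"] = period
    if extra:
        for k, v in extra.items():
            df[k] = v
    return ClusterTrialData(df=df, outcome_names=(outcome,))


def known_mean_fit(data, mu0=0.0, family="gaussian", link=None, delta_hat=0.0, se_hat=1.0,
                   theta=None, outcome=None):
    """A NuisanceFit with fixed (known) nuisance values, bypassing estimation.

    Useful for exactness checks: with the true means plugged in, the
    permutation test is exact under the randomization null.
    """
    name = outcome or data.outcome_names[0]
    spec = OutcomeSpec(name=name, family=family, link=link)
    return NuisanceFit(
        spec=spec,
        delta_hat=delta_hat,
        se_hat=se_hat,
        mu0_hat=mu0,
        beta_hat={},
        theta_hat=theta or {"sigma2": 1.0, "tau2": 0.0},
        covariance_structure="exchangeable" if data.n_periods == 1 else "ar_decay",
        converged=True,
        used_random_effects=False,
        eta_base=np.full(data.n_obs, mu0),
        treatment_indicator=data.treatment.copy(),
    )


@pytest.fixture(scope="session")
def model2_data():
    """One deterministic replicate of the Poisson+Gaussian parallel DGP."""
    return simulate_scenario(SimulationScenario(model_id=2), replicate_seed=42)


@pytest.fixture(scope="session")
def model2_fits(model2_data):
    import warnings
    from permcrt.nuisance_fit import fit_univariate_nuisance

    sc = SimulationScenario(model_id=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [fit_univariate_nuisance(model2_data, s) for s in sc.outcome_specs]
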