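"""Generators for the three benchmark cluster-trial data-generating processes.

All three DGPs randomize clusters 1:1 to two arms and share the mixed-model
structure eta = mu_j + delta_j D + theta_{j,c(t)} with exponential-family
outcomes:

model 1
    Two Gaussian outcomes measured post-intervention.  Cluster random-effect
    pairs are bivariate normal with cluster-level correlation pi and SDs
    tau_j; individual errors are bivariate normal with correlation rho and
    SDs sigma_j.  Defaults mu_j = 1, sigma_j^2 = 1, tau_j^2 = 0.05 give a
    marginal intraclass correlation of 0.05 per outcome.

model 2
    A Poisson (log link) and a Gaussian outcome with independent cluster
    effects (pi = 0), same intercepts and variance components as model 1.
    The Poisson outcome's ICC varies with the realized linear predictor
    (roughly 0.01-0.2 at these parameter values).

model 3
    Three outcomes (Poisson, Gaussian, Bernoulli-logit) over two periods with
    a baseline period: treated clusters switch on in period 2.  Cluster-period
    effects for each outcome are multivariate normal with temporal decay
    Cov(theta_ct, theta_ct') = tau_j^2 lambda^|t-t'| and zero cross-outcome
    correlation; a period fixed effect enters each linear predictor.
    Defaults mu_j = -1, tau_j = 1, lambda = 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .trial_data import ClusterTrialData, OutcomeSpec

__all__ = ["SimulationScenario", "simulate_scenario"]

_MODEL_J = {1: 2, 2: 2, 3: 3}


@dataclass
class SimulationScenario:
    """Parameters of one simulated trial scenario.

    Unset per-outcome fields receive the benchmark defaults for the chosen
    ``model_id``.  ``rho``/``pi`` are the individual- and cluster-level
    between-outcome correlations (model 1 only), ``lam`` the temporal decay
    of the cluster-period effects (model 3 only).
    """

    model_id: int
    clusters_per_arm: int = 7
    individuals_per_cluster: int = 20
    delta: tuple[float, ...] | None = None
    mu: tuple[float, ...] | None = None
    sigma: tuple[float, ...] | None = None
    tau: tuple[float, ...] | None = None
    rho: float = 0.0
    pi: float = 0.0
    lam: float = 0.7
    period_effect: float = 0.5
    n_sims: int = 1000
    M: int = 500
    Q: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_J:
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        J = _MODEL_J[self.model_id]
        if self.delta is None:
            self.delta = (0.0,) * J
        if self.mu is None:
            self.mu = (1.0,) * J if self.model_id != 3 else (-1.0,) * J
        if self.sigma is None:
            self.sigma = (1.0,) * J
        if self.tau is None:
            self.tau = (np.sqrt(0.05),) * J if self.model_id != 3 else (1.0,) * J
        for name in ("delta", "mu", "sigma", "tau"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != J:
                raise ValueError(f"{name} must have length {J} for model {self.model_id}")
            setattr(self, name, vals)
        if any(s < 0 for s in self.sigma) or any(t < 0 for t in self.tau):
            raise ValueError("standard deviations must be nonnegative")
        for r, lab in ((self.rho, "rho"), (self.pi, "pi"), (self.lam, "lam")):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{lab} must lie in [-1, 1], got {r}")
        if self.clusters_per_arm < 1 or self.individuals_per_cluster < 1:
            raise ValueError("cluster and individual counts must be positive")

    @property
    def n_outcomes(self) -> int:
        return _MODEL_J[self.model_id]

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(f"y{j + 1}" for j in range(self.n_outcomes))

    @property
    def outcome_specs(self) -> list[OutcomeSpec]:
        terms = ("period",) if self.model_id == 3 else ()
        families = {
            1: ("gaussian", "gaussian"),
            2: ("poisson", "gaussian"),
            3: ("poisson", "gaussian", "bernoulli"),
        }[self.model_id]
        return [OutcomeSpec(name=n, family=f, covariate_terms=terms)
                for n, f in zip(self.outcome_names, families)]


def _correlated_pairs(rng, n, sd1, sd2, corr, label):
    cov = np.array([[sd1**2, corr * sd1 * sd2], [corr * sd1 * sd2, sd2**2]])
    if np.any(np.linalg.eigvalsh(cov) < -1e-12):
        raise ValueError(f"implied {label} covariance is not positive semidefinite")
    return rng.multivariate_normal(np.zeros(2), cov, size=n)


def simulate_scenario(scenario: SimulationScenario, replicate_seed: int | None = None) -> ClusterTrialData:
    """Draw one trial dataset; identical (scenario, replicate_seed) pairs
    reproduce the dataset bit-identically.

    Which clusters are treated is re-randomized (uniformly over 1:1 splits)
    from the replicate seed, so the allocation itself is part of each
    replicate's randomness.
    """
    rng = np.random.default_rng(replicate_seed)
    cpa, n = scenario.clusters_per_arm, scenario.individuals_per_cluster
    C = 2 * cpa
    treated = np.zeros(C, dtype=bool)
    treated[rng.choice(C, size=cpa, replace=False)] = True
    mu, delta = np.array(scenario.mu), np.array(scenario.delta)
    sig, tau = np.array(scenario.sigma), np.array(scenario.tau)

    if scenario.model_id in (1, 2):
        cluster = np.repeat(np.arange(C), n)
        D = treated[cluster].astype(float)
        theta = _correlated_pairs(rng, C, tau[0], tau[1], scenario.pi, "cluster-effect")
        if scenario.model_id == 1:
            eps = _correlated_pairs(rng, C * n, sig[0], sig[1], scenario.rho, "error")
            cols = {
                f"y{j + 1}": mu[j] + delta[j] * D + theta[cluster, j] + eps[:, j]
                for j in range(2)
            }
        else:
            eta1 = mu[0] + delta[0] * D + theta[cluster, 0]
            y1 = rng.poisson(np.exp(eta1)).astype(float)
            y2 = mu[1] + delta[1] * D + theta[cluster, 1] + rng.normal(0.0, sig[1], C * n)
            cols = {"y1": y1, "y2": y2}
        df = pd.DataFrame({
            "cluster": cluster,
            "individual": np.arange(C * n),
            "treatment": D.astype(int),
            **cols,
        })
    else:
        T = 2
        cluster = np.repeat(np.arange(C), n * T)
        period = np.tile(np.repeat(np.arange(1, T + 1), n), C)
        D = (treated[cluster] & (period == 2)).astype(float)
        period_fx = scenario.period_effect * (period == 2)
        lam_cov = np.array([[1.0, scenario.lam], [scenario.lam, 1.0]])
        cols = {}
        for j in range(3):
            th = rng.multivariate_normal(np.zeros(T), tau[j] ** 2 * lam_cov, size=C)
            eta = mu[j] + delta[j] * D + period_fx + th[cluster, period - 1]
            if j == 0:
                cols["y1"] = rng.poisson(np.exp(eta)).astype(float)
            elif j == 1:
                cols["y2"] = eta + rng.normal(0.0, sig[1], len(eta))
            else:
                cols["y3"] = rng.binomial(1, special.expit(eta)).astype(float)
        df = pd.DataFrame({
            "cluster": cluster,
            "period": period,
            "individual": np.arange(len(cluster)),
            "treatment": D.astype(int),
            **cols,
        })

    return ClusterTrialData(df=df, outcome_names=scenario.outcome_names)
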