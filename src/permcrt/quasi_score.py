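"""Studentized quasi-score test statistics for arbitrary treatment allocations.

The building block is the per-cluster contribution to a signed sum of
generalized residuals r = Y - mu(delta*):

    weighted:    (D*_c o G_c) V_c^{-1} r_c  =  sum_k D*_k G_k (V_c^{-1} r)_k
    unweighted:  sum_{t,i} D*_ict r_ict

where D* is +1 on treated cluster-periods and -1 otherwise.  The studentized
statistic divides the total by the root sum of squared contributions, making
it scale-free — without studentization the variance of the statistic depends
on the null value being tested and the outcome's scale, which would unbalance
the confidence sets across outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nuisance_fit import ClusterCovariance
from .trial_data import ClusterTrialData

__all__ = [
    "ScoreDecomposition",
    "cluster_score_contributions",
    "studentized_statistic",
    "observation_score_vector",
    "DegenerateStatisticWarning",
]


class DegenerateStatisticWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ScoreDecomposition:
    """Per-cluster score contributions and the studentized total."""

    contributions: np.ndarray
    statistic: float
    mode: str


def observation_score_vector(
    residuals: np.ndarray,
    cov: ClusterCovariance | None,
    mode: str,
    G: np.ndarray | None = None,
) -> np.ndarray:
    """Per-observation vector u whose signed cluster sums are the contributions.

    unweighted: u = r;  weighted: u_k = G_k (V^{-1} r)_k.  Factoring the
    statistic this way lets many allocations be scored with one matrix
    product, since only the D* signs change across permutations.
    """
    if mode == "unweighted":
        return np.asarray(residuals, float)
    if mode == "weighted":
        if cov is None:
            raise ValueError("weighted mode requires a ClusterCovariance")
        return cov.weighted_observation_vector(np.asarray(residuals, float), G=G)
    raise ValueError(f"unknown mode {mode!r}")


def _normalize_allocation(data: ClusterTrialData, allocation: np.ndarray) -> np.ndarray:
    """Accept per-cluster +/-1 or (C, T) +/-1 signs; return (C, T)."""
    allocation = np.asarray(allocation, float)
    C, T = data.n_clusters, data.n_periods
    if allocation.ndim == 1:
        if len(allocation) != C:
            raise ValueError(f"allocation has length {len(allocation)}, expected C={C}")
        allocation = np.repeat(allocation[:, None], T, axis=1)
    if allocation.shape != (C, T):
        raise ValueError(f"allocation has shape {allocation.shape}, expected ({C}, {T})")
    if not np.isin(allocation, [-1.0, 1.0]).all():
        raise ValueError("allocation entries must be +1 (treated) or -1 (control)")
    return allocation


def cluster_score_contributions(
    data: ClusterTrialData,
    means: np.ndarray,
    cov: ClusterCovariance | None,
    allocation: np.ndarray,
    mode: str = "unweighted",
    outcome: str | None = None,
) -> ScoreDecomposition:
    """Per-cluster quasi-score contributions and studentized total.

    Parameters
    ----------
    means
        Per-observation null means (from ``null_marginal_means`` at the
        tested delta*); residuals are Y - means for the named ``outcome``
        (defaults to the data's single outcome).
    allocation
        D* signs: per-cluster vector of +/-1, or (C, T) signs per
        cluster-period.  Unweighted mode ignores ``cov``.
    """
    if outcome is None:
        if len(data.outcome_names) != 1:
            raise ValueError("outcome must be named when the data hold several outcomes")
        outcome = data.outcome_names[0]
    means = np.asarray(means, float)
    if len(means) != data.n_obs:
        raise ValueError("means length does not match number of observations")
    signs_ct = _normalize_allocation(data, allocation)
    residuals = data.outcome(outcome) - means
    u = observation_score_vector(residuals, cov, mode)
    signed = signs_ct[data.cluster_codes, data.period_codes] * u
    contributions = np.bincount(data.cluster_codes, weights=signed,
                                minlength=data.n_clusters)
    return ScoreDecomposition(
        contributions=contributions,
        statistic=studentized_statistic(contributions),
        mode=mode,
    )


def studentized_statistic(contributions: np.ndarray) -> float:
    """Sum of contributions divided by the root sum of their squares.

    Lies in [-sqrt(C), sqrt(C)]; antisymmetric under a global sign flip of
    the allocation; invariant to rescaling all contributions by a positive
    constant.  All-zero contributions yield 0 with a warning.
    """
    contributions = np.asarray(contributions, float)
    denom = np.sqrt(np.sum(contributions**2))
    if denom == 0.0:
        warnings.warn("all score contributions are zero; statistic set to 0",
                      DegenerateStatisticWarning, stacklevel=2)
        return 0.0
    return float(np.sum(contributions) / denom)
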