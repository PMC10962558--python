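"""Treatment re-allocation group, permuted statistic matrices, and p-values.

Under the randomization null the distribution of the data is invariant to the
set A of treatment allocations the randomization mechanism could have
produced.  For a parallel design A is every way of dividing the clusters into
two arms of the observed sizes; for a baseline-rollout design the re-labelled
clusters inherit the arms' treatment trajectories over periods.  Either the
full set is enumerated (small designs) or allocations are drawn uniformly
with replacement (Monte Carlo), and the statistic matrix T_j(a_m X) is formed
with residuals frozen at the null fits — only the D* signs change.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .nuisance_fit import ClusterCovariance, NuisanceFit, null_marginal_means
from .quasi_score import observation_score_vector
from .trial_data import ClusterTrialData

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "generate_allocations",
    "allocation_signs",
    "permutation_statistic_matrix",
    "statistics_for_memberships",
    "mc_pvalue",
]

SCHEMES = {"parallel_1to1", "parallel_general", "baseline_rollout"}


@dataclass(frozen=True)
class PermutationPlan:
    """How to explore the allocation set A.

    ``enumerate_all`` switches to full enumeration of A (identity included
    exactly once) when |A| is at most ``cap``; otherwise ``M`` allocations
    are drawn uniformly with replacement using ``seed``.
    """

    scheme: str = "parallel_general"
    M: int = 1000
    enumerate_all: bool = False
    cap: int = 20_000
    seed: int | None = None
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {sorted(SCHEMES)}")
        if self.M < 1:
            raise ValueError("M must be at least 1")


@dataclass
class PermutationResult:
    """Observed statistics, the permuted statistic matrix, and raw p-values."""

    observed: np.ndarray           # (J,)
    permuted: np.ndarray           # (M or L, J)
    p_raw: np.ndarray              # (J,)
    outcome_names: tuple[str, ...]
    sidedness: str = "two_sided"
    exact: bool = False

    @property
    def n_permutations(self) -> int:
        return self.permuted.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.permuted, columns=list(self.outcome_names))


def _design_counts(data: ClusterTrialData, plan: PermutationPlan):
    member = data.treated_clusters
    C, K = data.n_clusters, int(member.sum())
    if plan.scheme == "parallel_1to1" and 2 * K != C:
        raise ValueError("parallel_1to1 scheme requires equal arm sizes")
    if plan.scheme == "baseline_rollout" and data.n_periods < 2:
        raise ValueError("baseline_rollout scheme requires at least two periods")
    return C, K


def generate_allocations(data: ClusterTrialData, plan: PermutationPlan) -> np.ndarray:
    """Boolean arm-membership matrix, one allocation per row.

    Enumeration lists all C-choose-K arm splits; Monte-Carlo sampling draws
    allocations uniformly with replacement, reproducibly from ``plan.seed``.
    Arm sizes always match the observed allocation.
    """
    C, K = _design_counts(data, plan)
    if plan.enumerate_all:
        L = comb(C, K)
        if L > plan.cap:
            raise ValueError(
                f"|A| = {L} exceeds the enumeration cap ({plan.cap}); "
                "use Monte Carlo sampling instead"
            )
        out = np.zeros((L, C), dtype=bool)
        for m, idx in enumerate(combinations(range(C), K)):
            out[m, list(idx)] = True
        return out
    rng = np.random.default_rng(plan.seed)
    out = np.zeros((plan.M, C), dtype=bool)
    for m in range(plan.M):
        out[m, rng.choice(C, size=K, replace=False)] = True
    return out


def allocation_signs(data: ClusterTrialData, membership: np.ndarray) -> np.ndarray:
    """D* sign array (n_alloc, C, T) from boolean arm membership (n_alloc, C).

    Clusters assigned to the treated arm follow the treated arm's observed
    treatment trajectory over periods, control clusters the control arm's;
    signs are +1 where treatment is present and -1 otherwise.
    """
    membership = np.atleast_2d(np.asarray(membership, bool))
    treated_traj, control_traj = data.arm_trajectories
    D = np.where(membership[:, :, None], treated_traj[None, None, :],
                 control_traj[None, None, :])
    return 2.0 * D - 1.0


def statistics_for_memberships(
    data: ClusterTrialData,
    u: np.ndarray,
    membership: np.ndarray,
) -> np.ndarray:
    """Studentized statistics for many allocations from one observation vector.

    ``u`` is the per-observation score vector (residuals, or their weighted
    version); contributions are recomputed wholesale per allocation, with the
    denominator using the current allocation's signs.
    """
    C, T = data.n_clusters, data.n_periods
    U = np.bincount(data.cluster_period_index, weights=u, minlength=C * T).reshape(C, T)
    signs = allocation_signs(data, membership)               # (m, C, T)
    contrib = np.einsum("mct,ct->mc", signs, U)
    denom = np.sqrt(np.sum(contrib**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = np.where(denom > 0.0, contrib.sum(axis=1) / denom, 0.0)
    return stats


def permutation_statistic_matrix(
    data: ClusterTrialData,
    fits: list[NuisanceFit],
    covs: list[ClusterCovariance | None],
    delta_star: np.ndarray,
    plan: PermutationPlan,
    mode: str = "unweighted",
) -> PermutationResult:
    """Observed and permuted statistics for all outcomes at the null delta*.

    Residuals [Y - mu(delta*)] and the covariance weights are frozen from the
    null fits; row m holds all J statistics under allocation a_m.
    """
    delta_star = np.asarray(delta_star, float)
    if len(delta_star) != len(fits):
        raise ValueError("delta_star length must match the number of outcomes")
    membership = generate_allocations(data, plan)
    observed_membership = data.treated_clusters[None, :]

    J = len(fits)
    permuted = np.empty((membership.shape[0], J))
    observed = np.empty(J)
    for j, fit in enumerate(fits):
        mu = null_marginal_means(fit, data, delta_star[j])
        residuals = data.outcome(fit.spec.name) - mu
        u = observation_score_vector(residuals, covs[j], mode)
        permuted[:, j] = statistics_for_memberships(data, u, membership)
        observed[j] = statistics_for_memberships(data, u, observed_membership)[0]
        if not np.isfinite(permuted[:, j]).all():
            m_bad = int(np.flatnonzero(~np.isfinite(permuted[:, j]))[0])
            raise FloatingPointError(
                f"non-finite statistic for outcome {fit.spec.name!r} at permutation {m_bad}"
            )
        if not np.isfinite(observed[j]):
            raise FloatingPointError(f"non-finite observed statistic for {fit.spec.name!r}")

    p_raw = np.array([
        mc_pvalue(observed[j], permuted[:, j], plan.sidedness, exact=plan.enumerate_all)
        for j in range(J)
    ])
    return PermutationResult(
        observed=observed,
        permuted=permuted,
        p_raw=p_raw,
        outcome_names=tuple(f.spec.name for f in fits),
        sidedness=plan.sidedness,
        exact=plan.enumerate_all,
    )


def mc_pvalue(
    observed: float,
    permuted: np.ndarray,
    sidedness: str = "two_sided",
    exact: bool = False,
) -> float:
    """Permutation p-value with add-one Monte-Carlo estimator.

    Two-sided: (1 + #{m : |T(a_m X)| >= |T(X)|}) / (M + 1); one-sided uses the
    signed comparison in the stated direction.  Ties count toward the
    numerator.  With ``exact`` (full enumeration, identity included) the plain
    proportion over the group is returned instead — the identity term then
    plays the add-one role.
    """
    permuted = np.asarray(permuted, float)
    if not np.isfinite(observed) or not np.isfinite(permuted).all():
        raise ValueError("non-finite statistic passed to mc_pvalue")
    if sidedness == "two_sided":
        count = int(np.sum(np.abs(permuted) >= np.abs(observed)))
    elif sidedness == "greater":
        count = int(np.sum(permuted >= observed))
    elif sidedness == "less":
        count = int(np.sum(permuted <= observed))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    M = len(permuted)
    if exact:
        return count / M
    return (1 + count) / (M + 1)
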