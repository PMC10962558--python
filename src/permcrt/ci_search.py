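"""Robbins-Monro stochastic-approximation search for confidence-set limits.

A (1 - alpha) confidence set inverts the family of permutation tests: the
upper limit U_j sits where the hypothesis H_j: delta_j = U_j transitions from
rejection to non-rejection under the chosen multiplicity correction, and
likewise for the lower limit.  Rather than re-running a full permutation test
on a grid of null values, the search makes one permutation draw per step and
nudges each bound down by s_j alpha*/q when its hypothesis was rejected, or
up by s_j (1 - alpha*)/q when it was not (mirrored for lower limits).  The
1/q decay gives almost-sure convergence to the alpha* rejection quantile for
a fixed rejection probability, and the step-length constant

    k = 2 z_{1-alpha*} (2 pi)^{-1/2} exp(-z_{1-alpha*}^2 / 2)

(with z the standard-normal quantile) scales the steps to the current
distance between the bound and the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nuisance_fit import ClusterCovariance, NuisanceFit, null_marginal_means
from .quasi_score import observation_score_vector
from .permutation_engine import allocation_signs, generate_allocations, PermutationPlan
from .trial_data import ClusterTrialData

__all__ = [
    "SearchState",
    "ConfidenceSet",
    "step_constant",
    "update_bound",
    "search_confidence_set",
    "convergence_diagnostic",
]

METHODS = {"none", "bonferroni", "holm", "romano_wolf"}

# floor for a step length whose natural value k (bound - estimate) has the
# wrong sign (bound crossed the estimate), as a fraction of the outcome's SE
STEP_FLOOR_SE_FRACTION = 0.05


@dataclass
class SearchState:
    """Mutable state of one confidence-set search (both sides)."""

    upper: np.ndarray
    lower: np.ndarray
    q: int
    alpha_star_upper: np.ndarray
    alpha_star_lower: np.ndarray
    trace: np.ndarray = field(repr=False)   # (Q, J, 2): [..., 0]=lower, [..., 1]=upper
    seed: int | None = None


@dataclass
class ConfidenceSet:
    """Simultaneous confidence limits with search traces and diagnostics."""

    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    method: str
    mode: str
    converged: np.ndarray              # (J, 2) booleans, [:, 0]=lower, [:, 1]=upper
    trace: np.ndarray = field(repr=False)
    outcome_names: tuple[str, ...] = ()

    def contains(self, values: np.ndarray) -> bool:
        """Simultaneous containment of a full parameter vector."""
        values = np.asarray(values, float)
        return bool(np.all((self.lower <= values) & (values <= self.upper)))

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def trace_frame(self):
        import pandas as pd

        Q, J, _ = self.trace.shape
        names = list(self.outcome_names) or list(range(J))
        rec = []
        for j in range(J):
            for s, side in enumerate(("lower", "upper")):
                rec.append(pd.DataFrame({
                    "iteration": np.arange(1, Q + 1),
                    "outcome": names[j],
                    "side": side,
                    "value": self.trace[:, j, s],
                }))
        return pd.concat(rec, ignore_index=True)

    def plot_trace(self, path=None):
        """Trace plot per bound for visual convergence assessment."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        Q, J, _ = self.trace.shape
        names = list(self.outcome_names) or [str(j) for j in range(J)]
        fig, axes = plt.subplots(1, J, figsize=(4 * J, 3), squeeze=False)
        for j, ax in enumerate(axes[0]):
            ax.plot(self.trace[:, j, 1], label="upper")
            ax.plot(self.trace[:, j, 0], label="lower")
            ax.set_title(names[j])
            ax.set_xlabel("iteration")
        axes[0, 0].legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def step_constant(alpha_star: float) -> float:
    """Step-length constant k for a search targeting level alpha*."""
    if not 0.0 < alpha_star < 1.0:
        raise ValueError(f"alpha_star must be in (0, 1), got {alpha_star}")
    z = stats.norm.ppf(1.0 - alpha_star)
    return float(2.0 * z / np.sqrt(2.0 * np.pi) * np.exp(-0.5 * z * z))


def update_bound(
    bound: float,
    s: float,
    alpha_star: float,
    q: int,
    rejected: bool,
    side: str = "upper",
) -> float:
    """One Robbins-Monro update of a confidence limit.

    Upper side: bound - s alpha*/q if rejected, bound + s (1 - alpha*)/q
    otherwise; the lower side moves in the mirrored directions.
    """
    if q < 1:
        raise ValueError("iteration counter q must be >= 1")
    if side == "upper":
        return bound - s * alpha_star / q if rejected else bound + s * (1.0 - alpha_star) / q
    if side == "lower":
        return bound + s * alpha_star / q if rejected else bound - s * (1.0 - alpha_star) / q
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


def _alpha_star_schedule(method: str, alpha: float, J: int, rank: np.ndarray) -> np.ndarray:
    """Per-hypothesis alpha* given each hypothesis's current stepdown rank.

    none / romano_wolf: alpha.  bonferroni: alpha / J.  holm: alpha / (J - r)
    for the hypothesis of rank r = 0 (largest |T|), 1, ...
    """
    if method in ("none", "romano_wolf"):
        return np.full(J, alpha)
    if method == "bonferroni":
        return np.full(J, alpha / J)
    if method == "holm":
        return alpha / (J - rank)
    raise ValueError(f"unknown method {method!r}")


def _single_draw_rejections(method: str, t_obs: np.ndarray, t_perm: np.ndarray):
    """Rejection decisions from one permutation draw, plus stepdown ranks.

    romano_wolf: reject H_|1| if max_{j in K_1} |T_j(aX)| < |T_|1|(X)|, then
    continue down the ordering with the max over the not-yet-rejected set,
    stopping at the first non-rejection.  holm follows the same stepwise
    order but compares each hypothesis's own permuted statistic.  none and
    bonferroni compare |T_j(aX)| < |T_j(X)| for every j independently.
    """
    J = len(t_obs)
    a_obs, a_perm = np.abs(t_obs), np.abs(t_perm)
    order = np.lexsort((np.arange(J), -a_obs))
    rank = np.empty(J, dtype=int)
    rank[order] = np.arange(J)
    rejected = np.zeros(J, dtype=bool)
    if method in ("none", "bonferroni"):
        rejected = a_perm < a_obs
    elif method in ("romano_wolf", "holm"):
        remaining = list(order)
        for j in order:
            crit = a_perm[remaining].max() if method == "romano_wolf" else a_perm[j]
            if crit < a_obs[j]:
                rejected[j] = True
                remaining.remove(j)
            else:
                break
    else:
        raise ValueError(f"unknown method {method!r}")
    return rejected, rank


def search_confidence_set(
    data: ClusterTrialData,
    fits: list[NuisanceFit],
    covs: list[ClusterCovariance | None] | None = None,
    method: str = "romano_wolf",
    mode: str = "unweighted",
    alpha: float = 0.05,
    Q: int = 2000,
    seed: int | None = None,
    k_override: float | None = None,
    scheme: str = "parallel_general",
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConfidenceSet:
    """Search for the multiplicity-corrected confidence-set limits.

    Runs two independent Robbins-Monro processes (upper and lower limits,
    with permutation streams split from ``seed``), starting from the
    approximate uncorrected limits delta_hat_j +/- 2 SE_j.  At each step the
    observed statistics are re-evaluated at the current bound vector (the
    frozen nuisance fits supply the null means), one permutation is drawn,
    the correction's single-draw rejection rule is applied, and every bound
    is updated with its method-specific alpha*.

    ``start`` optionally overrides the (lower, upper) starting vectors; a
    start closer to the final limits shortens the slow 1/q transient, which
    is the search's main failure mode on hard problems.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if Q < 100:
        warnings.warn(f"Q={Q} search iterations is unreliable; use Q >= 100",
                      stacklevel=2)
    if covs is None:
        covs = [None] * len(fits)
    J = len(fits)
    delta_hat = np.array([f.delta_hat for f in fits])
    se = np.array([f.se_hat for f in fits])

    y = [data.outcome(f.spec.name) for f in fits]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]

    trace = np.empty((Q, J, 2))
    finals = {}
    converged = np.zeros((J, 2), dtype=bool)
    for s_idx, side in enumerate(("lower", "upper")):
        plan = PermutationPlan(scheme=scheme, M=Q, seed=child_seeds[s_idx])
        memberships = generate_allocations(data, plan)
        if start is not None:
            b = np.asarray(start[s_idx], float).copy()
        else:
            b = delta_hat + (2.0 * se if side == "upper" else -2.0 * se)
        for q in range(1, Q + 1):
            trace[q - 1, :, s_idx] = b
            t_obs = np.empty(J)
            t_perm = np.empty(J)
            member_q = memberships[q - 1][None, :]
            obs_member = data.treated_clusters[None, :]
            for j, fit in enumerate(fits):
                mu = null_marginal_means(fit, data, b[j])
                u = observation_score_vector(y[j] - mu, covs[j], mode)
                t_obs[j] = _stat_for_membership(data, u, obs_member)
                t_perm[j] = _stat_for_membership(data, u, member_q)
            rejected, rank = _single_draw_rejections(method, t_obs, t_perm)
            a_star = _alpha_star_schedule(method, alpha, J, rank)
            for j in range(J):
                k = k_override if k_override is not None else step_constant(a_star[j])
                raw_s = k * (b[j] - delta_hat[j]) if side == "upper" else k * (delta_hat[j] - b[j])
                s_len = max(raw_s, STEP_FLOOR_SE_FRACTION * se[j])
                b[j] = update_bound(b[j], s_len, a_star[j], q, bool(rejected[j]), side)
            if not np.all(np.isfinite(b)):
                raise FloatingPointError(
                    f"non-finite bound in {side} search at iteration {q}; "
                    f"trace: {trace[:q, :, s_idx]}"
                )
        finals[side] = b.copy()

    cs = ConfidenceSet(
        lower=finals["lower"],
        upper=finals["upper"],
        alpha=alpha,
        method=method,
        mode=mode,
        converged=converged,
        trace=trace,
        outcome_names=tuple(f.spec.name for f in fits),
    )
    cs.converged, _ = convergence_diagnostic(trace, widths=cs.widths)
    return cs


def _stat_for_membership(data, u, membership) -> float:
    # local import-free fast path of permutation_engine.statistics_for_memberships
    C, T = data.n_clusters, data.n_periods
    U = np.bincount(data.cluster_period_index, weights=u, minlength=C * T).reshape(C, T)
    signs = allocation_signs(data, membership)[0]
    contrib = (signs * U).sum(axis=1)
    denom = np.sqrt(np.sum(contrib**2))
    return float(contrib.sum() / denom) if denom > 0.0 else 0.0


def convergence_diagnostic(
    trace: np.ndarray,
    window: float = 0.2,
    tol: float = 0.05,
    widths: np.ndarray | None = None,
):
    """Flag bounds whose search has not settled.

    A bound is non-converged when, over the final ``window`` fraction of the
    trace, either its range or the drift implied by a linear fit exceeds
    ``tol`` times the interval width (falling back to the bound's own scale
    when the width is degenerate).  Returns a (J, 2) boolean array
    ([:, 0]=lower, [:, 1]=upper) and a drift summary of the same shape.
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 3 or trace.shape[0] < 2:
        raise ValueError("trace must be a (Q, J, 2) array with Q >= 2")
    Q, J, _ = trace.shape
    n_tail = max(int(round(window * Q)), 2)
    tail = trace[-n_tail:]
    if widths is None:
        widths = trace[-1, :, 1] - trace[-1, :, 0]
    scale = np.where(np.abs(widths) > 1e-12, np.abs(widths),
                     np.maximum(np.abs(trace[-1]).max(axis=1), 1.0))
    x = np.arange(n_tail)
    converged = np.zeros((J, 2), dtype=bool)
    drift = np.zeros((J, 2))
    for j in range(J):
        for s in range(2):
            series = tail[:, j, s]
            rng_ = series.max() - series.min()
            slope = np.polyfit(x, series, 1)[0]
            drift[j, s] = slope * n_tail
            converged[j, s] = (rng_ <= tol * scale[j]) and (abs(drift[j, s]) <= tol * scale[j])
    return converged, drift
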