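"""Bonferroni, Holm, and Romano-Wolf stepdown corrections for multiple outcomes.

Bonferroni and Holm act on the raw (permutation) p-values; the Romano-Wolf
stepdown acts on the full permuted statistic matrix, estimating each step's
critical value from the permutation distribution of the maximum statistic
over the not-yet-rejected hypotheses.  Because the max over a subset is never
larger than the implicit Bonferroni bound, Romano-Wolf adjusted p-values are
(up to Monte-Carlo noise) no larger than Holm's, which are no larger than
Bonferroni's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from statsmodels.stats.multitest import multipletests

from .permutation_engine import PermutationResult

__all__ = ["CorrectionResult", "adjust_bonferroni_holm", "romano_wolf_stepdown",
           "stepdown_critical_value"]


@dataclass
class CorrectionResult:
    """Adjusted p-values and rejection decisions for one correction method."""

    method: str
    p_adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float
    order: np.ndarray | None = None          # stepdown ordering (hypothesis indices)
    critical_values: np.ndarray | None = None
    p_raw: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self, outcome_names=None):
        import pandas as pd

        J = len(self.p_adjusted)
        return pd.DataFrame({
            "outcome": list(outcome_names) if outcome_names is not None else list(range(J)),
            "p_raw": self.p_raw if self.p_raw is not None else [np.nan] * J,
            f"p_{self.method}": self.p_adjusted,
            "rejected": self.rejected,
        })


def adjust_bonferroni_holm(
    p_raw: np.ndarray,
    method: str = "holm",
    alpha: float = 0.05,
) -> CorrectionResult:
    """Classical corrections of a vector of p-values.

    Bonferroni: min(J p_j, 1).  Holm: sort ascending, multiply the r-th
    smallest by (J - r + 1), enforce a nondecreasing cumulative maximum, cap
    at 1, and map back to the original order.
    """
    p_raw = np.asarray(p_raw, float)
    if ((p_raw < 0) | (p_raw > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in {"bonferroni", "holm", "none"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "none":
        p_adj = p_raw.copy()
    else:
        _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method=method)
    return CorrectionResult(
        method=method,
        p_adjusted=p_adj,
        rejected=p_adj <= alpha,
        alpha=alpha,
        p_raw=p_raw,
    )


def stepdown_critical_value(max_stats: np.ndarray, alpha: float) -> float:
    """Estimated (1 - alpha) critical value from permuted max-statistics.

    Uses the ceil(L (1 - alpha))-th smallest value, clamped to [1, L]
    (a conservative reading of the "nearest integer" rank rule).
    """
    s = np.sort(max_stats)
    L = len(s)
    rank = min(max(ceil(L * (1.0 - alpha)), 1), L)
    return float(s[rank - 1])


def romano_wolf_stepdown(result: PermutationResult, alpha: float = 0.05) -> CorrectionResult:
    """Resampling-based stepdown adjusted p-values and decisions.

    Hypotheses are ordered by |observed statistic| descending (ties broken by
    original outcome index).  At step r the permutation distribution of
    max_{j in K_r} |T_j(a X)| over the not-yet-rejected set K_r gives the
    adjusted p-value for H_|r| as the (add-one) proportion of maxima at least
    |T_|r|(X)|; adjusted p-values are made nondecreasing down the order, and
    rejection proceeds while p <= alpha, stopping at the first non-rejection.

    One-sided variants use signed comparisons instead of absolute values.
    """
    obs = result.observed
    perm = result.permuted
    J = len(obs)
    if result.sidedness == "two_sided":
        obs_c, perm_c = np.abs(obs), np.abs(perm)
    elif result.sidedness == "greater":
        obs_c, perm_c = obs, perm
    else:  # less: flip so larger means more extreme
        obs_c, perm_c = -obs, -perm

    order = np.lexsort((np.arange(J), -obs_c))  # descending, index tie-break
    p_adj_ordered = np.empty(J)
    crit = np.empty(J)
    remaining = list(order)
    add_one = 0 if result.exact else 1
    denom = perm.shape[0] + add_one
    for r, j in enumerate(order):
        max_stats = perm_c[:, remaining].max(axis=1)
        count = int(np.sum(max_stats >= obs_c[j]))
        p_adj_ordered[r] = (add_one + count) / denom
        crit[r] = stepdown_critical_value(max_stats, alpha)
        remaining.remove(j)
    p_adj_ordered = np.maximum.accumulate(p_adj_ordered)  # monotone down the order
    p_adj_ordered = np.minimum(p_adj_ordered, 1.0)

    p_adjusted = np.empty(J)
    p_adjusted[order] = p_adj_ordered

    rejected = np.zeros(J, dtype=bool)
    for r, j in enumerate(order):  # stepdown semantics: stop at first failure
        if p_adj_ordered[r] <= alpha:
            rejected[j] = True
        else:
            break
    return CorrectionResult(
        method="romano_wolf",
        p_adjusted=p_adjusted,
        rejected=rejected,
        alpha=alpha,
        order=order,
        critical_values=crit,
        p_raw=result.p_raw,
    )
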