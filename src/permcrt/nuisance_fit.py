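"""Per-outcome mixed-model fits whose estimates are frozen for permutation inference.

For each outcome a univariate generalized linear mixed model with a cluster
random intercept is fitted:

    eta_ict = mu0 + delta * D_ct + X_ict' beta + theta_ct,
    Y_ict ~ P(h^{-1}(eta_ict)),

where D_ct indicates treatment of cluster c in period t.  Gaussian outcomes
use statsmodels' MixedLM (maximum likelihood by default).  Poisson and
Bernoulli outcomes use an in-package marginal-likelihood fit with a Laplace
approximation to the per-cluster random-intercept integral (optionally
adaptive Gauss-Hermite quadrature with ``nagq`` nodes) — the same
approximation lme4's glmer uses by default.

The fitted nuisance parameters (mu0, beta, variance components) are computed
once and re-used for every permutation: the validity of the permutation test
requires that everything except the tested effect be invariant to the
re-allocations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve

from .trial_data import ClusterTrialData, OutcomeSpec, ValidationError

__all__ = [
    "NuisanceFit",
    "ClusterCovariance",
    "FitError",
    "fit_univariate_nuisance",
    "null_marginal_means",
    "build_cluster_covariance",
]


class FitError(RuntimeError):
    """Model estimation failed in a way that cannot be recovered from."""


def _invlink(link: str, eta: np.ndarray) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    if link == "logit":
        return special.expit(eta)
    raise ValueError(f"unknown link {link!r}")


def _variance_function(family: str, mu: np.ndarray, sigma2: float) -> np.ndarray:
    """Conditional variance of Y given the linear predictor."""
    if family == "gaussian":
        return np.full_like(mu, sigma2)
    if family == "poisson":
        return mu
    if family == "bernoulli":
        return mu * (1.0 - mu)
    raise ValueError(f"unknown family {family!r}")


def link_weights(link: str, mu: np.ndarray) -> np.ndarray:
    """Elements of G: (d h^{-1} / d eta)^{-1} evaluated at the fitted means.

    identity -> 1;  log -> 1/mu;  logit -> (mu (1 - mu))^{-1}.
    """
    if link == "identity":
        return np.ones_like(mu)
    if link == "log":
        return 1.0 / mu
    if link == "logit":
        return 1.0 / (mu * (1.0 - mu))
    raise ValueError(f"unknown link {link!r}")


@dataclass
class NuisanceFit:
    """Frozen per-outcome estimates used to build permutation statistics.

    ``eta_base`` is the fitted linear predictor with the treatment term
    removed (mu0 + X'beta, including any period effects), so the null
    predictor at delta* is ``eta_base + delta* * D``.
    """

    spec: OutcomeSpec
    delta_hat: float
    se_hat: float
    mu0_hat: float
    beta_hat: dict[str, float]
    theta_hat: dict[str, float]
    covariance_structure: str
    converged: bool
    used_random_effects: bool
    eta_base: np.ndarray = field(repr=False)
    treatment_indicator: np.ndarray = field(repr=False)
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_hat):
            raise FitError(f"non-finite treatment effect estimate for {self.spec.name!r}")
        if not self.se_hat > 0:
            raise FitError(f"standard error must be positive for {self.spec.name!r}")
        for k, v in self.theta_hat.items():
            if k in ("sigma2", "tau2") and v < 0:
                raise FitError(f"negative variance component {k}={v} for {self.spec.name!r}")

    def summary_frame(self) -> pd.DataFrame:
        rows = {"delta": self.delta_hat, "se": self.se_hat, "mu0": self.mu0_hat}
        rows.update({f"beta[{k}]": v for k, v in self.beta_hat.items()})
        rows.update({f"theta[{k}]": v for k, v in self.theta_hat.items()})
        return pd.DataFrame({"outcome": self.spec.name, "parameter": list(rows), "value": list(rows.values())})


@dataclass
class ClusterCovariance:
    """Per-cluster working covariance V_c, its inverse, and link weights G.

    Assembled once from the frozen variance components and re-used for every
    permutation.  ``rows`` holds the observation indices of each cluster in
    the order the V_c matrices are laid out.
    """

    rows: list[np.ndarray]
    V: list[np.ndarray]
    Vinv: list[np.ndarray]
    G: np.ndarray
    structure: str

    def weighted_observation_vector(self, residuals: np.ndarray, G: np.ndarray | None = None) -> np.ndarray:
        """Per-observation u_k = G_k * (V^{-1} r)_k, so that the weighted
        quasi-score contribution of cluster c is sum_k D*_k u_k."""
        G = self.G if G is None else G
        u = np.empty_like(residuals)
        for idx, Vinv in zip(self.rows, self.Vinv):
            u[idx] = G[idx] * (Vinv @ residuals[idx])
        return u


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _design(data: ClusterTrialData, spec: OutcomeSpec):
    """Columns: intercept, treatment, covariates, period-2..T dummies."""
    n = data.n_obs
    cols = [np.ones(n), data.treatment]
    names = ["intercept", "treatment"]
    for term in spec.covariate_terms:
        if term == "period":
            for t in range(1, data.n_periods):
                cols.append((data.period_codes == t).astype(float))
                names.append(f"period_{data.period_values[t]}")
        else:
            cols.append(data.df[term].to_numpy(float))
            names.append(term)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(f"singular design for {spec.name!r}: collinear terms among {names}")
    return X, names


# ---------------------------------------------------------------------------
# Laplace / adaptive Gauss-Hermite marginal likelihood for non-Gaussian GLMMs
# ---------------------------------------------------------------------------

def _conditional_loglik_terms(family: str, y: np.ndarray, eta: np.ndarray):
    """Pointwise log f(y|eta), mean, and conditional variance."""
    if family == "poisson":
        mu = np.exp(eta)
        ll = y * eta - mu - special.gammaln(y + 1.0)
        return ll, mu, mu
    if family == "bernoulli":
        mu = special.expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        return ll, mu, mu * (1.0 - mu)
    raise ValueError(family)


def _cluster_modes(family, y, xb, cluster_codes, C, tau2, theta0=None, n_iter=25):
    """Vectorized Newton search for the per-cluster random-intercept modes."""
    theta = np.zeros(C) if theta0 is None else theta0.copy()
    for _ in range(n_iter):
        eta = xb + theta[cluster_codes]
        _, mu, v = _conditional_loglik_terms(family, y, eta)
        grad = np.bincount(cluster_codes, weights=y - mu, minlength=C) - theta / tau2
        hess = -np.bincount(cluster_codes, weights=v, minlength=C) - 1.0 / tau2
        step = grad / hess
        theta -= np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return theta


def _marginal_loglik(params, family, y, X, cluster_codes, C, nagq, gh=None, offset=0.0):
    """Laplace (nagq=1) or adaptive Gauss-Hermite marginal log-likelihood.

    params = (beta..., log tau).
    """
    beta, log_tau = params[:-1], params[-1]
    tau = np.exp(log_tau)
    tau2 = tau * tau
    xb = X @ beta + offset
    theta = _cluster_modes(family, y, xb, cluster_codes, C, tau2)
    eta = xb + theta[cluster_codes]
    ll, _, v = _conditional_loglik_terms(family, y, eta)
    g_mode = np.bincount(cluster_codes, weights=ll, minlength=C) - theta**2 / (2.0 * tau2)
    neg_g2 = np.bincount(cluster_codes, weights=v, minlength=C) + 1.0 / tau2
    if nagq <= 1:
        # log integral ~ g(mode) + 0.5 log(2 pi / -g'') ; divide by tau sqrt(2 pi)
        return float(np.sum(g_mode - np.log(tau) - 0.5 * np.log(neg_g2)))
    nodes, weights = gh
    sd = 1.0 / np.sqrt(neg_g2)  # (C,)
    t_nodes = theta[:, None] + np.sqrt(2.0) * sd[:, None] * nodes[None, :]  # (C, K)
    g_nodes = np.empty_like(t_nodes)
    for k in range(len(nodes)):
        eta_k = xb + t_nodes[cluster_codes, k]
        ll_k, _, _ = _conditional_loglik_terms(family, y, eta_k)
        g_nodes[:, k] = (
            np.bincount(cluster_codes, weights=ll_k, minlength=C)
            - t_nodes[:, k] ** 2 / (2.0 * tau2)
        )
    log_int = special.logsumexp(
        g_nodes + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1
    ) + 0.5 * np.log(2.0) + np.log(sd)
    return float(np.sum(log_int - np.log(tau) - 0.5 * np.log(2.0 * np.pi)))


def _fit_glmm_marginal(family, y, X, names, cluster_codes, C, nagq=1, offset=0.0):
    """Maximize the Laplace/AGQ marginal likelihood over (beta, log tau)."""
    import statsmodels.api as sm

    fam = sm.families.Poisson() if family == "poisson" else sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=fam, offset=np.broadcast_to(offset, y.shape)).fit()
    start = np.append(glm.params, np.log(0.25))
    gh = None
    if nagq > 1:
        gh = np.polynomial.hermite.hermgauss(nagq)

    def nll(p):
        with np.errstate(over="ignore"):
            val = _marginal_loglik(p, family, y, X, cluster_codes, C, nagq, gh, offset)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(nll, start, method="L-BFGS-B",
                            options={"maxiter": 200, "ftol": 1e-11})
    if not np.all(np.isfinite(res.x)):
        raise FitError("marginal likelihood optimization diverged")

    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(res.x, nll)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(res.x), np.nan)
    p = len(names)
    beta = dict(zip(names, res.x[:p]))
    tau2 = float(np.exp(2.0 * res.x[p]))
    se_beta = dict(zip(names, se[:p]))
    return beta, se_beta, tau2, -res.fun, bool(res.success)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def _fit_one_model(data, spec, y, X, names, *, reml, random_effects, nagq, offset=0.0):
    """One (possibly mixed) fit; returns (beta, se_beta, theta, loglik,
    converged, used_random_effects).  ``offset`` is added to the linear
    predictor without a free coefficient (used for null-constrained fits)."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    C = data.n_clusters
    beta = se_beta = None
    theta_hat: dict[str, float] = {}
    loglik = np.nan
    converged = True
    used_re = random_effects

    if random_effects:
        try:
            if spec.family == "gaussian":
                # identity link: an offset is just a shift of the response
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mm = MixedLM(y - offset, X, groups=data.cluster_codes).fit(reml=reml)
                beta = dict(zip(names, mm.fe_params))
                se_beta = dict(zip(names, mm.bse_fe))
                theta_hat = {"sigma2": float(mm.scale),
                             "tau2": float(np.asarray(mm.cov_re)[0, 0])}
                loglik = float(mm.llf)
                converged = bool(mm.converged)
            else:
                beta, se_beta, tau2, loglik, converged = _fit_glmm_marginal(
                    spec.family, y, X, names, data.cluster_codes, C,
                    nagq=nagq, offset=offset,
                )
                theta_hat = {"sigma2": 1.0, "tau2": tau2}
            if any(not np.isfinite(s) or s <= 0 for s in se_beta.values()):
                raise FitError("unusable standard error from mixed fit")
        except (FitError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(
                f"mixed fit failed for {spec.name!r} ({exc}); "
                "falling back to a fixed-effects GLM",
                stacklevel=3,
            )
            used_re = False
            converged = False
            beta = None

    if beta is None:  # fixed-effects-only path
        fam = {
            "gaussian": sm.families.Gaussian(),
            "poisson": sm.families.Poisson(),
            "bernoulli": sm.families.Binomial(),
        }[spec.family]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=fam, offset=np.broadcast_to(offset, y.shape)).fit()
        beta = dict(zip(names, glm.params))
        se_beta = dict(zip(names, glm.bse))
        theta_hat = {"sigma2": float(glm.scale) if spec.family == "gaussian" else 1.0,
                     "tau2": 0.0}
        loglik = float(glm.llf)
    return beta, se_beta, theta_hat, loglik, converged, used_re


def fit_univariate_nuisance(
    data: ClusterTrialData,
    spec: OutcomeSpec,
    *,
    delta_star_ref: float = 0.0,
    reml: bool = False,
    random_effects: bool = True,
    covariance_structure: str | None = None,
    theta: dict[str, float] | None = None,
    nagq: int = 1,
) -> NuisanceFit:
    """Fit the univariate models for one outcome and freeze the null estimates.

    Two fits are performed.  The unconstrained model (treatment effect free)
    supplies the point estimate delta_hat and its standard error.  The
    null-constrained model — treatment entering only as the fixed offset
    ``delta_star_ref * D`` — supplies the nuisance estimates (mu0, beta,
    variance components) that define the frozen null means and covariance
    weights.  Estimating the nuisance under the null keeps the studentized
    statistics' permutation distributions comparable across outcomes, which
    the stepdown's max statistic relies on.

    Parameters
    ----------
    delta_star_ref
        The null value at which the nuisance is estimated (0 for the usual
        test of no effect).
    reml
        Use restricted ML for Gaussian outcomes (default False: plain ML).
    random_effects
        If False, fit fixed-effects-only GLMs; variance components for the
        weighted statistic must then come from ``theta``.  Mixed fits that
        fail to converge fall back to this automatically with a warning.
    theta
        Optional variance-component overrides, e.g. ``{"sigma2": 1.0,
        "tau2": 0.05, "lam": 0.7}``; merged over the fitted values.
    nagq
        Number of adaptive quadrature nodes for non-Gaussian mixed fits;
        1 means the Laplace approximation.
    """
    data.check_outcome_family(spec)
    y = data.outcome(spec.name)
    X, names = _design(data, spec)
    if covariance_structure is None:
        covariance_structure = "exchangeable" if data.n_periods == 1 else "ar_decay"
    if covariance_structure == "ar_decay" and data.n_periods < 2:
        raise ValidationError("ar_decay covariance requires more than one period")

    if spec.family != "gaussian" and np.ptp(y) == 0.0:
        raise FitError(
            f"outcome {spec.name!r} is constant ({y[0]}); the {spec.family} "
            "fit is degenerate (boundary estimate)"
        )

    if not np.isfinite(delta_star_ref):
        raise ValueError("delta_star_ref must be finite")

    # unconstrained fit: point estimate and SE of the treatment effect
    beta_full, se_full, _, _, conv_full, used_re_full = _fit_one_model(
        data, spec, y, X, names,
        reml=reml, random_effects=random_effects, nagq=nagq,
    )

    # null-constrained fit: nuisance frozen for permutation inference
    keep = [i for i, n in enumerate(names) if n != "treatment"]
    X0, names0 = X[:, keep], [names[i] for i in keep]
    offset = delta_star_ref * data.treatment
    beta0, _, theta_hat, loglik0, conv0, used_re0 = _fit_one_model(
        data, spec, y, X0, names0,
        reml=reml, random_effects=random_effects, nagq=nagq, offset=offset,
    )

    if theta:
        theta_hat.update(theta)
    if data.n_periods > 1:
        theta_hat.setdefault("lam", 1.0)

    eta_base = X0 @ np.array([beta0[n] for n in names0])

    return NuisanceFit(
        spec=spec,
        delta_hat=float(beta_full["treatment"]),
        se_hat=float(se_full["treatment"]),
        mu0_hat=float(beta0["intercept"]),
        beta_hat={k: float(v) for k, v in beta0.items() if k != "intercept"},
        theta_hat=theta_hat,
        covariance_structure=covariance_structure,
        converged=conv_full and conv0,
        used_random_effects=used_re_full and used_re0,
        eta_base=eta_base,
        treatment_indicator=data.treatment.copy(),
        loglik=loglik0,
    )


def null_marginal_means(fit: NuisanceFit, data: ClusterTrialData, delta_star: float) -> np.ndarray:
    """Fitted means under the null H0: delta = delta*.

    Applies the inverse link to ``eta_base + delta* * D``; the frozen nuisance
    estimates are never re-fitted for a new delta*.
    """
    if not np.isfinite(delta_star):
        raise ValueError(f"delta_star must be finite, got {delta_star}")
    eta = fit.eta_base + delta_star * fit.treatment_indicator
    return _invlink(fit.spec.link, eta)


def build_cluster_covariance(
    fit: NuisanceFit,
    data: ClusterTrialData,
    delta_star: float = 0.0,
) -> ClusterCovariance:
    """Assemble V_c per cluster from the frozen variance components.

    exchangeable:  V_c = diag(v_i) + tau^2 * J  (for Gaussian outcomes the
    diagonal is sigma^2 + tau^2 and off-diagonals tau^2).
    ar_decay:      entries tau^2 * lambda^|t - t'| off the diagonal, with the
    conditional variance v_i added on the diagonal.

    Inverses are computed once by dense Cholesky (clusters are small) and
    re-used for every permutation.
    """
    structure = fit.covariance_structure
    if structure == "ar_decay" and data.n_periods < 2:
        raise ValidationError("ar_decay covariance requires more than one period")
    mu = null_marginal_means(fit, data, delta_star)
    v = _variance_function(fit.spec.family, mu, fit.theta_hat.get("sigma2", 1.0))
    tau2 = fit.theta_hat.get("tau2", 0.0)
    lam = fit.theta_hat.get("lam", 1.0)
    G = link_weights(fit.spec.link, mu)

    rows, Vs, Vinvs = [], [], []
    for c in range(data.n_clusters):
        idx = np.flatnonzero(data.cluster_codes == c)
        if structure == "independence" or tau2 == 0.0:
            Vc = np.diag(v[idx])
        elif structure == "exchangeable":
            Vc = np.full((len(idx), len(idx)), tau2)
            Vc[np.diag_indices_from(Vc)] += v[idx]
        elif structure == "ar_decay":
            t = data.period_codes[idx].astype(float)
            Vc = tau2 * lam ** np.abs(t[:, None] - t[None, :])
            Vc[np.diag_indices_from(Vc)] += v[idx]
        else:
            raise ValueError(f"unknown covariance structure {structure!r}")
        try:
            cf = cho_factor(Vc)
            Vinv = cho_solve(cf, np.eye(len(idx)))
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"covariance matrix for cluster {data.cluster_labels[c]!r} "
                "is not positive definite"
            ) from exc
        rows.append(idx)
        Vs.append(Vc)
        Vinvs.append(Vinv)
    return ClusterCovariance(rows=rows, V=Vs, Vinv=Vinvs, G=G, structure=structure)
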