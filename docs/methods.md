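# Methods

`permcrt` provides family-wise inference for cluster randomized trials (CRTs)
with multiple outcomes: permutation-test p-values with Bonferroni, Holm, or
Romano-Wolf stepdown corrections, and simultaneous confidence sets found by a
Robbins-Monro stochastic-approximation search.  This note records the model,
the statistics, the numerical choices, and what the built-in simulations do
and do not demonstrate.

## Model and statistics

Each outcome j is modelled by a generalized linear mixed model

    eta_ict = mu0 + delta D_ct + X'_ict beta + theta_ct,
    Y_ict ~ P_j(h^{-1}(eta_ict)),

for individual i in cluster c at period t, where D_ct indicates treatment and
theta_ct is a cluster(-period) random effect.  Supported family/link pairs
are Gaussian/identity, Poisson/log, and Bernoulli/logit.

The test of H_j: delta_j = delta* is based on a quasi-score statistic: a
signed sum of generalized residuals r = Y - mu(delta*), where the signs D*
are +1 on treated cluster-periods and -1 otherwise.  Two variants are
available:

- weighted: per-cluster contributions (D*_c o G_c) V_c^{-1} r_c, with G the
  derivative weights of the link and V_c a working covariance built from the
  fitted variance components;
- unweighted: plain signed sums of residuals per cluster-period.

Both are studentized — divided by the root sum of squared per-cluster
contributions — so their permutation null distributions are scale-free and
comparable across outcomes.  That comparability is what the stepdown's max
statistic and the balance of the confidence sets rely on.

Permutation inference re-scores the statistic under re-allocations of the
cluster treatment labels consistent with the randomization (all arm-size
preserving splits; baseline-rollout designs re-assign which clusters follow
the switched-on trajectory).  Small groups are enumerated (default cap
20 000 allocations); otherwise M allocations are drawn uniformly with
replacement and the add-one Monte-Carlo estimator
p = (1 + #{m: |T(a_m X)| >= |T(X)|}) / (M + 1) is used.  Ties count toward
the numerator.

## Nuisance estimation: two fits per outcome

Permutation validity requires the nuisance parameters (mu0, beta, variance
components) to be invariant across permutations, so they are estimated once
and frozen.  Two fits are performed per outcome:

1. an unconstrained fit (treatment effect free) giving the point estimate
   delta_hat and its model-based standard error — used for the naive Wald
   comparison, the search starting values, and the step lengths;
2. a null-constrained fit, with treatment entering only as the fixed offset
   delta*_ref · D, giving the nuisance estimates that define the frozen null
   means mu(delta*) = h^{-1}(eta_base + delta* D).

The second, score-test-style fit matters: plugging unconstrained estimates
into the null predictor leaves the fitted treatment contrast in the null
residuals, which inflates each outcome's studentized denominator by a
different amount and visibly distorts the stepdown's cross-outcome max
(simulated Romano-Wolf FWER drops to roughly half the nominal level).  With
the null-constrained nuisance all corrections hold their nominal rates.
Null means are never re-fitted for a different tested delta*; the frozen
eta_base is combined with delta* D through the link.

Gaussian outcomes are fitted by maximum likelihood (REML available via a
flag) with statsmodels' MixedLM.  Poisson and Bernoulli outcomes use an
in-package marginal-likelihood fit for the random-intercept model: the
per-cluster integral is approximated by a Laplace approximation around the
vectorized-Newton mode (optionally adaptive Gauss-Hermite quadrature with
`nagq` nodes), and the (beta, log tau) profile is maximized by L-BFGS with a
finite-difference Hessian for standard errors.  On fixture data both stages
agree with lme4 (glmer's default is the same Laplace approximation) to four
or more decimals.  Mixed fits that fail fall back to a fixed-effects GLM
with a warning; variance components can then be supplied externally, which
is also how the three-outcome baseline-period benchmark is analysed (GLM
point estimates, working covariance from known components).

The working covariance V_c is exchangeable for single-period designs
(diagonal sigma^2 + tau^2, off-diagonal tau^2 in the Gaussian case; the
conditional variance v(mu) replaces sigma^2 for non-Gaussian outcomes) and
temporally decaying for multi-period designs: Cov(theta_ct, theta_ct') =
tau^2 lambda^|t - t'| with zero cross-outcome correlation.  Inverses are
computed once per cluster by dense Cholesky and re-used for every
permutation.

## Corrections

Bonferroni and Holm act on the raw permutation p-values (via statsmodels'
multipletests).  The Romano-Wolf stepdown orders hypotheses by |observed
statistic| (ties broken by outcome index), and at each step takes the
permutation distribution of the maximum |statistic| over the
not-yet-rejected set; adjusted p-values are made monotone down the ordering
and rejection stops at the first failure.  The quantile rank for critical
values is ceil(L(1 - alpha)) clamped to [1, L] — the conservative reading of
the "nearest integer" rule.  By construction the adjusted p-values order as
Romano-Wolf <= Holm <= Bonferroni on the same statistics.

## Confidence-set search

A (1-alpha) confidence set inverts the corrected tests.  Upper and lower
limits are searched by independent Robbins-Monro processes (separate
permutation streams split from the master seed), started at
delta_hat_j +/- 2 SE_j.  Each step evaluates the observed statistics at the
current bound vector, draws one permutation, applies the correction's
single-draw rejection rule (Romano-Wolf: stepwise comparison against the max
over not-yet-rejected hypotheses; Bonferroni/Holm: per-hypothesis comparison
at their alpha* levels — an interpretation, since only the Romano-Wolf rule
is fully specified in the literature this follows), and nudges each bound by
s_j alpha*/q on rejection or s_j (1 - alpha*)/q otherwise.  The alpha*
schedule is alpha (none, Romano-Wolf), alpha/J (Bonferroni), or
alpha/(J - r) for the rank-r hypothesis (Holm).  Step lengths are refreshed
each iteration as s_j = k(alpha*) |bound - delta_hat_j| with
k = 2 z_{1-alpha*} (2 pi)^{-1/2} exp(-z^2_{1-alpha*}/2) (k(0.05) ~ 0.3392,
user-overridable); when a bound crosses the point estimate the step length
is floored at 0.05 SE_j to avoid sign pathologies.

Properties worth knowing:

- The equilibrium of each bound solves "P(single-draw rejection) = 1 -
  alpha*", which matches the fixed point of the full stepdown test
  (adjusted p at the limits equal to alpha); this was verified directly
  against a bisection on enumerated adjusted p-values.
- The 1/q step decay makes the transient slow: from the 2-SE start the
  bounds can take thousands of iterations to reach limits near 2.5-3 SE.
  Q >= 2000 is the default; hard problems (more outcomes, poor starts) show
  exactly the non-convergence the trace diagnostics are designed to catch.
  `convergence_diagnostic` flags a bound when the range or fitted drift of
  the final 20% of its trace exceeds 5% of the interval width.
- Coverage is evaluated as simultaneous containment of the full true
  parameter vector.

## Synthetic benchmark trials

Three data-generating processes drive verification, all with 1:1 cluster
randomization re-drawn each replicate:

1. two Gaussian outcomes, cluster-effect pairs with correlation pi and SDs
   tau_j = sqrt(0.05), individual errors with correlation rho and unit SDs,
   intercepts mu_j = 1 — marginal ICC 0.05;
2. a Poisson (log link) and a Gaussian outcome with independent cluster
   effects, same components — the Poisson ICC varies with the realized
   linear predictor (~0.01-0.2);
3. three outcomes (Poisson, Gaussian, Bernoulli) over two periods with a
   baseline period (treated clusters switch on in period 2), cluster-period
   effects with temporal decay lambda = 0.7, tau_j = 1, mu_j = -1, and a
   period fixed effect.  The period effect's magnitude is not part of the
   benchmark's specification; 0.5 is used, and the analysis model adjusts
   for period so the operating characteristics are insensitive to it.

Default design sizes are 7 clusters per arm of 20 individuals (the
small-sample regime where model-based standard errors are biased) and 14 per
arm of 10.  What these generators do not emulate: unequal cluster sizes
(supported by the data model, off by default), missing data, covariate
imbalance, and non-exchangeable individual-level dependence — passing the
simulation checks says nothing about those features of real trials.

## Scaled-down verification sizes

The packaged checks estimate FWER from 400-1000 replicates with 500-1000
permutations per test, and family-wise coverage from 150 replicates with
Q = 1000 search steps — sizes chosen so the whole suite runs on a laptop.
Tolerances are three binomial Monte-Carlo standard errors plus 0.01 (the
extra slack reflects the nested randomness of permutation tests and searches
inside each replicate).  At these sizes the Romano-Wolf coverage estimate
sits a little below its large-replication reference value: the frozen
nuisance (never re-fitted at the candidate delta* during the search, by
design) costs some joint calibration in replicates with extreme point
estimates.  The FWER checks are unaffected.

## Known limitations

- No small-sample corrections for model-based standard errors (the naive
  arm exists precisely to show their absence matters); permutation inference
  is the remedy offered.
- Restricted randomization is supported only through user-supplied
  allocation lists; there is no constraint engine.
- No within-cluster permutation, multi-arm designs, gatekeeping, or
  intersection-union testing.
- The Bonferroni/Holm single-draw rejection rules in the search are an
  interpretation (documented above); the Romano-Wolf rule is the one pinned
  down by the literature this implements.
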