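# Methods

## Model

The package estimates a two-equation ordered probit in which the category
cut-points are themselves functions of covariates (a hierarchical ordered
probit, HOPIT). The latent health index is

    h*_i = beta' x_i + eps_i,     eps_i ~ N(0, 1),

where `x_i` collects binary long-term-condition indicators, two dummies
for a recent short-term limitation ("a lot", "a little"; reference "no"),
and product terms for 2- and 3-way condition combinations that pass a
prevalence screen. Identification fixes the error scale at 1 and omits a
latent intercept — the intercept is absorbed into the first cut-point, so
the latent equation has no constant. The cut-points follow the
exponential-increment parametrization

    tau_i1 = lambda_1 + gamma_1' z_i
    tau_ij = tau_{i,j-1} + exp(lambda_j + gamma_j' z_i),   j = 2..4,

with `z_i` the reporting covariates (group dummies, age-band-by-sex
cells, deprivation terciles, healthcare-use indicators, wave dummies).
Each dummy family drops one baseline level. No column may appear in both
`x` and `z`; the construction code enforces this and re-checks it after
any covariate reallocation. The exponential increments guarantee
tau_1 < tau_2 < tau_3 < tau_4 for all parameter values, so the optimizer
never needs ordering constraints.

The observed level is `j` when tau_{j-1} <= h* < tau_j. Estimation
maximizes the survey-weighted log-likelihood (weights enter
multiplicatively per respondent), so duplicating a row is exactly
equivalent to doubling its weight, and rescaling all weights rescales the
log-likelihood without moving the maximizer.

## Interaction screen

Candidate interactions are all 2- and 3-way products of condition
indicators. A candidate enters the latent design when its weighted joint
prevalence (share of survey weight on rows with all parents equal to 1)
is at least 1% by default. Each order is screened on its own joint
prevalence — a triple is not conditioned on its sub-pairs passing.
Weighted prevalence is the default for consistency with weighted
estimation; an unweighted switch exists (`weighted=False`). Output
ordering is lexicographic by parent names, making the screen invariant to
row order and to uniform weight rescaling.

## Estimation and numerics

- Starting values are deterministic: beta = gamma = 0, and lambda set so
  that the implied cut-points match the weighted cumulative outcome
  distribution through the probit quantile function. Refits on identical
  input therefore reproduce identical estimates.
- The optimizer is L-BFGS-B on the negative weighted log-likelihood with
  the analytic gradient (chain rule through the exponentiated
  increments); on a reported failure it restarts once and finally falls
  back to Nelder-Mead. After termination a few Newton steps, restricted
  to directions whose observed-information eigenvalues are well above
  zero, polish the optimum to near machine precision. This is what makes
  weight-scale invariance of the maximizer hold to ~1e-8 in practice.
- Interval probabilities are evaluated in the numerically favourable
  normal tail (survivor form when the interval lies in the right tail)
  and floored at 1e-300 before logs; threshold exponents are clipped at
  ±30 with a logged warning. Feasible parameters therefore never produce
  −inf likelihoods.
- The convergence flag requires the gradient max-norm to be below
  1e-4 × (1 + |lnL|). An absolute gradient tolerance would not scale: a
  weighted log-likelihood of magnitude 1e5 cannot meaningfully be driven
  to a 1e-5 gradient.
- The covariance matrix is the inverse observed information (numerical
  Hessian of the analytic gradient, central differences), inverted
  through its eigendecomposition with eigenvalues floored at 1e-10 times
  the largest. Nearly unidentified directions — e.g. the fourth-cut slope
  of a group with a handful of respondents at the most severe level —
  then receive very large positive variances rather than an indefinite
  matrix, and a warning is issued. A design-based sandwich estimator
  (`vcov_type="sandwich"`) is available because survey weights make the
  naive information model-based.
- The null model for fit indices is the weighted intercept-only ordered
  probit (four free cut-points), fitted with the same machinery.

## Threshold contrasts and bootstrap

Profiles hold every reporting covariate at its weighted sample proportion
(unweighted switch available), zero the group block for the baseline
profile z0, and switch exactly one group dummy on for z1. The contrast
recursion uses the linear form for the first cut and cumulative
exponential differences for cuts 2–4; the recursive line applies from
j = 2 (applying it at j = 1 would double-define the first contrast), and
the result equals the difference of the two threshold vectors identically.

The bootstrap draws coefficient vectors from a multivariate normal at the
estimates with the estimated covariance (symmetrized, eigenvalues floored
at zero), recomputes the contrast per draw, and reports both a percentile
95% interval and point ± 1.96 × bootstrap SE. A contrast is flagged
significant only when both intervals exclude zero. Fewer than 40 draws:
the percentile interval is refused (NaN), the SE interval kept. Defaults:
1,000 draws, seeded.

## Fit metrics

- Standardized coefficients: each latent slope divided by the range of
  the fitted index over the observed sample, so the affinely shifted
  index spans [0, 1]. The range is taken over observed rows, not over all
  theoretically possible covariate combinations.
- Likelihood ratio index: McFadden's 1 − lnL_full / lnL_null by default.
  The alternative reading 1 − lnL_null / lnL_full ("inverse_ratio") is
  computable but is negative whenever the model improves on the null,
  which is incompatible with the positive magnitudes conventionally
  reported; McFadden is therefore the default.
- Count R2: weighted share of rows whose modal predicted category equals
  the observed one; exact ties resolve to the less severe level (measure
  zero under continuous parameters).
- AIC = 2k − 2 lnL with k = |beta| + 4 + 4·|gamma columns|.

## Synthetic data generator

The generator emulates the structure of a large English general-practice
survey: 15 condition indicators with marginal prevalences between 0.14%
(dementia) and 17% (high blood pressure), correlated through a one-factor
Gaussian copula (loading 0.5) so that multimorbidity and hence screenable
interactions occur at realistic rates; a 3-level recent-limitation item
loaded on the same factor; five ethnic-group shares dominated by one
majority group (0.88/0.06/0.027/0.008/0.023); ten age-band-by-sex cells;
deprivation terciles; healthcare-use indicators; wave dummies; and
heterogeneous lognormal survey weights with unit mean (sigma 0.5),
independent of outcomes by default. Outcomes are generated by running the
two-equation model forward with known parameters; hidden columns carry
the true latent draws and thresholds, so generator self-consistency
(reclassifying the hidden draws reproduces the outcomes exactly) is
testable bit-for-bit.

Default truth values are round numbers at plausible scales: condition
slopes 0.2–0.5, limitation dummies 0.8/0.4, cut-point intercepts giving
tau = (1.0, 1.6, 2.1, 2.6) at z = 0 (placing most respondents in the
least severe level), and group reporting shifts of +0.2/+0.3/0/+0.15 on
the first cut for the four non-baseline groups with smaller effects on
later cuts.

What the generator does not emulate: real comorbidity structure beyond a
single factor, informative weighting (a dependence knob exists but is off
by default), item missingness, and any calibration to real survey joint
distributions. Passing recovery tests therefore demonstrates estimator
correctness under the model's assumptions, not robustness to their
violation.

## Simulation-study configurations and problem sizes

Two reduced configurations keep repeated fitting affordable:

- `SyntheticConfig.compact()`: 5 conditions, group + deprivation
  reporting covariates, single wave — 35 free parameters.
- The balanced two-group design (50/50 shares, one +0.2 first-cut shift)
  used for estimator validation: balanced allocation maximizes the
  information on the group contrast, which is what a recovery experiment
  is meant to measure; the highly unbalanced default shares are kept for
  the structural end-to-end runs.

The shipped checks use: ordered-probit reduction at n = 5,000 (unit
weights, since the reference implementation is unweighted); gradient
checks at n = 200; single-replicate recovery at n = 50,000; interval
coverage with 100 replicates at n = 20,000 and 500 bootstrap draws; and
the five-dimension end-to-end run at n = 20,000 with 500 draws.

## Known limitations

- Only the five-level outcome scale is supported (four cut-points).
- Rows with any missing modelled field are dropped (complete-case); no
  imputation.
- No panel or random-effects structure: repeated cross-sections are
  pooled with wave dummies.
- The latent equation's identification rests on the disjointness of the
  two covariate sets; the package enforces the mechanics but cannot test
  the substantive exclusion restriction.
- Very small group-by-level cells leave some cut-point slopes nearly
  unidentified; these surface as floored-eigenvalue warnings and very
  large standard errors rather than as failures.
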