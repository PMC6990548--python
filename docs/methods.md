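# Methods

## Model

The outcome is a child-level Bernoulli indicator (anaemia, defined by
altitude-adjusted haemoglobin strictly below 11 g/dL for ages 6–59
months). The linear predictor is structured additive:

```
logit(pi) = x' beta + f_age(age) + f_str(district) + f_unstr(district)
```

Fixed effects are dummy coded against fixed reference levels (gender:
male; malaria RDT: negative; residence: urban; mother's education: none;
head gender: male; toilet: no facilities) with continuous covariates
(household size, wealth index, altitude in 100 m units, EVI, LST)
entering linearly and unstandardised. Model classes: M1 (GLM — every
covariate linear, including age), M2 (GAM — age replaced by a P-spline
smooth), M3 (geoadditive — M2 plus the two spatial effects).

Priors: `beta ~ N(0, 1000)` elementwise; spline coefficients get a
second-order random-walk prior with precision `tau2_r K`, `K = D2'D2`
(first-order available); the structured district effect gets the
intrinsic CAR prior with joint precision `tau2_str Q`, `Q = diag(n_h) -
A` for rook adjacency `A`; the unstructured effect is iid Gaussian with
precision `tau2_unstr`; every precision has a Gamma(a=1, b=0.001)
hyperprior.

## Inference

Pólya-Gamma data augmentation yields an exact Gibbs sampler. Per sweep:

1. `omega_i ~ PG(1, eta_i)` for every child. PG draws use the truncated
   infinite-convolution-of-gammas representation with 100 terms, the
   omitted tail replaced by its expectation (mean-exact; missing tail
   variance is O(10^-6) of the total). The closed-form mean
   `tanh(z/2)/(2z)` is verified by Monte Carlo in the tests.
2. The full latent Gaussian block `(beta, alpha, u_str, f_unstr)` is
   drawn jointly from its Gaussian conditional with precision
   `X' Omega X + P` and mean solving that system against `X'(y - 1/2)`,
   via one Cholesky factorisation.
3. Each precision is drawn from its conjugate conditional
   `Gamma(a + rank/2, b + quad/2)` with `rank` the penalty rank
   (`M - d` for the random walk, `n - c` for the ICAR with `c`
   connected components, `n` for the iid effect).

Identifiability constraints are built into the parametrisation rather
than imposed afterwards: the spline block is sampled in the subspace
where the basis-column-mean weighted coefficient sum vanishes (so the
fitted smooth averages to zero over the training data), and the
structured effect is sampled in the eigenbasis of `Q` restricted to
positive eigenvalues, which enforces per-component sum-to-zero exactly
and pins the effect of any isolated district to zero (the ICAR prior is
undefined at degree-0 nodes). Only the unstructured effect needs the
classical fix: it is recentred every sweep with the mean absorbed into
the intercept. Without these constraints the joint precision would be
singular (the basis rows sum to one and the district indicators sum to
the intercept column).

Degenerate inputs: a non-positive-definite conditional precision
(complete separation, collinear design) or any non-finite draw aborts
with a diagnostic rather than returning garbage. Rows with missing
values in used columns are dropped with a logged count. Chains are
reproducible from a single integer seed.

DIC uses the plug-in at the posterior mean of the linear predictor:
`pD = Dbar - D(eta_bar)`, `DIC = Dbar + pD`; the identities hold to
machine precision by construction. Negative `pD` warns rather than
errors. Model comparison refuses fits trained on different rows
(outcome-hash check).

## Synthetic surveys

The generator runs the model forwards over a nested two-stage cluster
design: districts (default 60, rook-adjacent grid) contain clusters
(default 4) of households (default 17) with 1 + Poisson children each
(mean 2, so ~8 000 children). Cluster-level covariates (residence,
altitude, EVI, LST) are shared within cluster, household covariates
within household. Survey weights are inverse cluster-selection
probabilities (selection ~ U(0.2, 1)), constant within cluster; they
feed only the weighted-prevalence descriptives — the likelihood is
unweighted, matching the model statement.

Default effect sizes are the adjusted odds ratios of the anaemia
analysis the package is built around (malaria positive 4.401, female
0.873, wealth 0.858 per SD, ...) taken as generative log-odds truths;
spatial precisions default to tau2_str = 853.58 and tau2_unstr = 3.84,
i.e. a weak structured and dominant unstructured effect; the intercept
(0.222) was calibrated once, numerically, so overall prevalence sits
near 53.7% under the covariate defaults, and is not revisited. The age
curve is a centred Gaussian bump peaking at 10 months (amplitude 1.2,
scale 8 months) — a pronounced rise from 6 to 10 months followed by a
decline, centred to sum to zero on the integer grid 6..59. Structured
effects are drawn from the ICAR distribution via the eigendecomposition
of `Q` with zero eigenvalues dropped (the density is only proper on the
sum-to-zero subspace).

What the generator does not emulate: non-response, country-realistic
joint covariate distributions, within-cluster outcome correlation beyond
what shared covariates and district effects induce, or DHS recode file
formats. Passing tests therefore demonstrate correctness of the
machinery and recoverability of effects under the stated design, not
robustness to real-survey misspecification.

## Screening and descriptives

Univariate screening fits one unweighted ML logistic regression per
covariate and applies a likelihood-ratio test (single test per
multi-level factor) at the 10% level; complete separation is flagged and
the covariate kept. VIFs are computed among the continuous covariates
only (`1/(1-R^2)` from OLS on the others; a single covariate has VIF 1
by convention; flag at 4). Weighted prevalence CIs use a logit-scale
Wald interval with effective sample size `(sum w)^2 / sum w^2`, which
keeps bounds inside (0, 100); exact boundary proportions fall back to a
Clopper–Pearson-style one-sided bound. Full Taylor-linearised survey
variance estimation is out of scope.

## Reporting conventions

Intervals are equal-tailed 95% credible intervals. AOR intervals are
computed on the coefficient scale and exponentiated (quantiles are
equivariant under monotone maps, which keeps the sign-flip/reciprocal
symmetry exact); the AOR point estimate is the posterior mean of
`exp(beta)` (configurable to `exp` of the mean). Significance stars mean
the interval excludes 1 (odds ratios) or 0 (effects). The spatial
component with the smaller precision (larger variance) is reported as
dominant. District summaries export to CSV always and to GeoJSON when
polygons are supplied, with unmatched polygons flagged `no_data`.

## Numerical and design choices

* Spline default: cubic basis, 17 interior intervals (20 basis
  functions), RW2 — about 20 bases with the penalty controlling
  smoothness is standard P-spline practice; the knot count is
  configurable. Boundary knots are clamped (repeated), and evaluation
  outside the knot span is an error, not extrapolation.
* Rook contiguity (shared edge, not corner) operationalises "share a
  common boundary" for polygon input; the GAL file, when supplied, is
  taken as authoritative.
* The Gamma(a, b) hyperprior on each precision is the log-gamma-on-the-
  log-scale convention, giving conjugate Gamma conditionals.
* Problem sizes in the test suite: replicate-fit checks use surveys of
  ~4 300–8 200 children over the 60-district grid with chains of
  300–1 200 iterations; the oracle-equivalence check uses 50 000 draws
  on a 20-observation, 2-parameter posterior against dense grid
  quadrature.

## Known limitations

* Single-site conjugate updates of the smoothing precisions mix slowly
  between rough and smooth explanations of the age effect. At ~8 000
  children the posterior can genuinely favour a monotone-from-6-months
  curve over the bump (the 6-vs-10-month contrast of the truth is only
  ~0.26 on the log-odds scale), in which case the curve's argmax sits at
  the boundary even though its correlation with the truth stays above
  0.95. Larger surveys resolve the peak reliably.
* The BYM decomposition identifies the *total* spatial effect much
  better than its split: signal placed on spatially contiguous districts
  is attributed to the structured component regardless of which
  component generated it. Tests of unstructured-effect recovery
  therefore use scattered, mutually non-adjacent districts.
* No cluster- or household-level random effects (the predictor has
  none); no WAIC/LOO; no adaptive knot placement; no interactions.
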