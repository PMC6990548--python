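# geoadditive

Bayesian geoadditive logistic regression for district-level disease
mapping, built around the analysis of childhood anaemia in household
surveys. It is aimed at epidemiologists and biostatisticians who want a
fully testable, self-contained implementation of the structured additive
regression workflow — including a synthetic survey generator, so every
stage runs end-to-end without access-restricted DHS/MIS microdata.

## The model

For child *k* in household *j*, cluster *i* and district *h*, the binary
outcome (anaemic: altitude-adjusted Hb < 11 g/dL) follows

```
logit(pi_hijk) = x'_hijk beta + f_age(age_hijk) + f_str(s_h) + f_unstr(s_h)
```

* `beta` — linear fixed effects (child gender, malaria RDT result,
  household size, residence, mother's education, head-of-household
  gender, toilet facility, wealth index, cluster altitude per 100 m,
  EVI, LST), vague N(0, 1000) priors.
* `f_age` — Bayesian P-spline: cubic B-splines on equally spaced knots
  with a second-order random-walk prior (precision `tau2_r K`,
  `K = D2'D2`).
* `f_str` — structured (spatially correlated) district effect with the
  intrinsic CAR prior: conditionally Gaussian around the mean of its
  neighbours, joint precision `tau2_str Q` where `Q = diag(n_h) - A`.
* `f_unstr` — unstructured iid Gaussian district effect, precision
  `tau2_unstr` (together with `f_str`, the BYM decomposition).
* Every precision gets a Gamma(1, 0.001) hyperprior; sum-to-zero
  constraints on the smooth and both spatial effects identify the
  intercept.

Three nested candidates are compared by DIC: **M1** (GLM, all covariates
linear), **M2** (GAM, smooth age), **M3** (geoadditive, M2 + spatial
effects).

Inference is a Pólya-Gamma data-augmentation Gibbs sampler: augmenting
each Bernoulli observation with `omega_i ~ PG(1, eta_i)` makes the whole
latent Gaussian block conditionally Gaussian and every precision
conditionally Gamma, so the sampler is exact (no approximation beyond
Monte Carlo) and is verified in the test suite against dense grid
quadrature of small posteriors.

## Worked example

```python
from geoadditive import SynthDesign, MCMCConfig, simulate_survey, fit_model
from geoadditive.model_eval import dic
from geoadditive.reporting import aor_table, variance_table

children, graph, effects = simulate_survey(SynthDesign(seed=1))
fit = fit_model(children, "m3", graph=graph,
                mcmc=MCMCConfig(n_iter=700, burn_in=200, seed=2))
print(aor_table(fit).set_index("term").loc["malaria_rdt=positive"])
print(variance_table(fit)[1])
print(dic(fit))
```

On one synthetic survey of 8 208 children over a 60-district grid this
prints a malaria AOR near the generative truth of 4.401 (e.g. posterior
mean 4.70 with 95% CrI 4.18–5.29 at the seeds above), the dominance note
`the unstructured spatial effect is dominant (tau2_str = 444.84,
tau2_unstr = 3.70)`, and a DIC around 9 962 — below the GAM (10 388) and
GLM (10 431) fits of the same data, so model choice lands on the
geoadditive model. An AOR is "significant" when its 95% credible
interval excludes 1; district effects are classed significantly
positive/negative when their interval excludes 0.

The same pipeline is available from the shell:

```sh
geoadd simulate --out children.csv --graph-out districts.gal --seed 1
geoadd screen   --data children.csv --out screening.csv
geoadd fit      --data children.csv --graph districts.gal --model m3 --out fit_m3
geoadd report   --fit fit_m3 --out report/
```

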