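# Methods

## Model

`msocc` implements a hierarchical multispecies site-occupancy model
with annual dynamics and imperfect detection. The latent state
`z[i,k,t]` indicates whether species *i* truly occupies site *k* in
year *t*; it is Bernoulli with probability `psi[i,k,t]`. Detections
`y[i,k,t,j]` on visit *j* are Bernoulli with probability
`z[i,k,t] * p[i,k,t,j]`, so a species absent from a site-year can never
be detected there and a recorded detection forces `z = 1` in the
posterior.

Detection varies by treatment and year and by linear and quadratic
terms in the survey date (logit scale):

    logit p = a0_i + aT_i*TRT_k + aY_{i,t} + aD1_i*d + aD2_i*d^2

where `d` is the Julian date centred and scaled to mean 0, SD 1 across
all visits, and the quadratic term is the square of the scaled value.
Year effects use reference coding (year-1 offset fixed at 0) for
identifiability.

Occupancy varies by management district and by a treatment × year
interaction, with autologistic dependence on the previous year's state:

    logit psi (t = 1) = b0_i + alpha_i*TRT_k + bD_i*DIST_k
    logit psi (t > 1) = theta_i*z[i,k,t-1] + theta'_i*(1 - z[i,k,t-1])
                        + alpha_i*TRT_k + bD_i*DIST_k + bTY_{i,t}*TRT_k

The two-term dynamic intercept is algebraically a single intercept plus
an autologistic slope, `logit psi = theta' + (theta - theta')*z_prev +
...`; with `theta = theta'` it reduces exactly to a static model with
intercept `theta` (this equivalence is tested). The treatment × year
offsets `bTY` apply only after the base year, again reference-coded;
the district effect is additive in all years (no district × year
interaction — the design does not support estimating one).

Every species-level coefficient family f is exchangeable across
species: `coef_i ~ Normal(mu_f, sigma_f)`. The community-level
`(mu_f, sigma_f)` are the quantities of headline interest, in
particular `mu[occ_treatment]`, the community mean treatment effect on
occupancy (logit scale).

The model conditions on the set of observed species; it does not
augment the community with never-detected species, so "richness" means
richness of the observed species pool.

## Priors and the four scenarios

Hyper-SDs have uniform(0, 10) priors. Hyper-means have diffuse
normal(0, 10) priors, with two exceptions that define the scenarios:

* the detection-intercept hyper-mean always carries a beta prior on the
  probability scale (with the logit-scale Jacobian `m(1-m)` applied in
  the density): beta(1, 1) — uniform — when diffuse, or a beta fitted
  to a previous study's species-specific posterior means when informed;
* the occupancy treatment-effect hyper-mean carries normal(0, 10) when
  diffuse or a fitted normal(m, s) when informed.

The four scenarios are: `diffuse`, `informed_detection`,
`informed_treatment`, `informed_both`. Elicitation fits the beta by the
method of moments (closed form; maximum-likelihood refinement
available) and the normal by sample mean and SD (n−1 denominator, SD
floored at 1e-3 with a warning for degenerate samples). A beta fit
requires sample variance < m(1−m); at least 3 species are required for
any fit. The original study's numeric summaries are not published, so
the package ships a synthetic stand-in generator (detection means from
Beta(2, 5) — per-visit detection mostly 0.1–0.6; treatment effects from
Normal(0.5, 0.5) — modest positive effects) plus a reader for
user-supplied two-column files.

## Sampler

Metropolis-within-Gibbs, one cycle per iteration:

1. **Latent states.** Each `z[i,k,t]` without a detection is redrawn
   from its exact full conditional, combining the year-t occupancy
   term (conditional on `z` at t−1), the probability of the all-zero
   detection record, and — except in the final year — the year-t+1
   autologistic term evaluated at both candidate states. The sweep runs
   over years ascending, vectorised over species and sites, so each
   conditional always uses the current neighbouring states.
2. **Species coefficients.** Random-walk Metropolis per coefficient
   family, proposing all species simultaneously; per-species
   accept/reject is valid because species blocks are conditionally
   independent given the hypers. Proposal scales (one per family) adapt
   toward 0.44 acceptance by Robbins–Monro steps in batches of 50
   iterations during burn-in only, leaving the post-burn-in kernel
   stationary.
3. **Hyper-parameters.** Normal-prior hyper-means are conjugate normal
   draws; the beta-informed detection-intercept hyper-mean and all
   hyper-SDs (uniform support enforced by rejection) use random-walk
   Metropolis with burn-in-adapted scales.

Chains are initialised with `z = 1` where detected and Bernoulli(0.5)
elsewhere, hypers at `mu = 0, sigma = 1`, and species coefficients
dispersed around the initial hypers. Each chain consumes an independent
substream spawned from the configured seed, so runs are bit-reproducible.

Configurations: the original study's full-length setting (3 chains ×
500,000 iterations, 250,000 burn-in, thin 50) is provided as
`STUDY_CONFIG`;
routine runs and the test suite use desk-scale settings (`DESK_CONFIG`:
3 × 5,000 / 2,500 / thin 5; several tests use smaller, explicitly
stated configurations). Desk-scale chains on the full design take
roughly 20 s each; short chains can leave rhat well above 1 for weakly
identified hyper-SDs, which the diagnostics report rather than hide.

Correctness is established in distribution, not by matching any
particular sampler's internals: marginal posteriors on a
1-species/2-site problem match dense-grid numerical integration within
Monte-Carlo error, latent-path frequencies on a 2-year toy match
exhaustive enumeration, Metropolis accept/reject decisions match an
independent evaluation of the joint density, prior-only sweeps pass a
Kolmogorov–Smirnov test against the community normal, and the conjugate
hyper-mean moments match the closed form.

## Derived statistics

All community summaries are computed per posterior draw of `z`, then
summarised by the posterior median and central 95% interval:

* **Richness**: `sum_i z[i,k,t]` per site-year.
* **Richness contrasts**: per draw, mean richness over treated sites
  minus mean over control sites, per district × year (6 cells in the
  default design).
* **Similarity**: Dice coefficient `2|A∩B| / (|A| + |B|)` between two
  sites' assemblages (Jaccard available behind a flag). The Dice form
  is used because it is the classical "proportion of species shared"
  coefficient; pairs are summarised by class (control–control,
  control–treatment, treatment–treatment).
* **Turnover** (per site, year t > 1): fraction of the current
  community absent the previous year.
* **Local extinction** (per site, year t < T): fraction of the current
  community absent the next year.
* **Local survival** (per species): fraction of occupied site-years
  (before the final year) still occupied the next year, pooled over
  sites and year pairs — the complement of the pooled extinction
  fraction, displayed one value per species. A per-year variant can be
  had by slicing the draws. Survival is defined forward in time
  (persistence from t to t+1), the complement of extinction.
* **Effect tables**: per-species and hyper-mean posterior median, 2.5%
  and 97.5% quantiles, and a contains-zero flag (the evidence
  criterion for species-level effects).

0/0 cases (empty communities) propagate as missing values and are
excluded from summaries, never imputed. Every statistic is verified
against an independent brute-force nested-loop recomputation.

## Diagnostics

Gelman–Rubin potential scale reduction factor per scalar parameter on
the post-burn-in thinned draws, classic multi-chain form without chain
splitting (W = mean within-chain variance, B = N × variance of chain
means, rhat = sqrt(((N−1)/N·W + B/N) / W)); the variance ratio is
floored at 1 because values below 1 arise only from finite-sample
noise, and zero within-chain variance is reported as undefined (NaN)
rather than 1.

The posterior predictive check simulates replicate detection data from
each retained draw (thinned to at most 500), reduces observed and
replicate data to species × site detection counts, and compares
Freeman–Tukey discrepancies `sum (sqrt(n) - sqrt(e))^2` against the
expected counts under the draw; the Bayesian p-value is the fraction of
draws with replicate discrepancy at least the observed one. The
discrepancy statistic is an argument, so other choices plug in.

## Synthetic data generator

The generator reproduces the study design: a balanced treatment ×
district allocation (`n_sites_per_cell` per cell; the default 6 gives
24 sites), 3 years, 3 visits, and integer visit dates drawn uniformly
in the survey window (day of year 135–182), sorted within each
site-year so visits are in temporal order, then centred and scaled.
One date is shared by all species per (site, year, visit) — a single
point-count visit records the whole community. The generator operates
at stand level; within-stand survey stations and habitat covariates
are not simulated.

Default ground-truth hypers place the community in a realistic
songbird regime: detection intercept −0.85 (≈0.30 per-visit detection)
with SD 1.0 (species vary widely in detectability), occupancy intercept
0.5, treatment effect +1.0 with SD 0.5, district 0.3, persistence 2.0 /
colonization −1.0 (high year-to-year survival, as observed in sedentary
breeding communities), weak date effects (−0.2 linear and quadratic),
all other means 0, all other SDs 0.5. Values are configurable per
family.

What the generator does **not** emulate: unmodelled heterogeneity
(observer effects, abundance-driven detection, spatial correlation
among stands, within-stand station structure). Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification —
the posterior predictive check is the tool for the latter.

## Numerical choices

* Probabilities are clipped 1e-12 from {0, 1} before logs in the public
  likelihood functions; the sampler's kernels use the
  `log p = -log(1+e^-eta)` form, which is overflow-safe without
  clipping.
* An impossible state (detection with `z = 0`) yields log-likelihood
  −inf, not an exception.
* `sigma <= 0` yields prior density −inf; the generator, by contrast,
  accepts `sigma = 0` as a degenerate point mass (useful for
  deterministic truths).
* Quantiles use the default linear-interpolation estimator; medians of
  statistics with missing draws use NaN-aware reductions.
* Indices are 0-based internally; emitted tables are 1-based with
  calendar year labels.

## Test and script problem sizes

The test suite and `scripts/acceptance.py` run everything at desk
scale, chosen as the package's own routine setting: recovery uses 20
replicates of the full 27 × 24 × 3 × 3 design at 5,000 iterations
(single chain per replicate), the pipeline reproducibility check uses
2 × 1,200 iterations per scenario, and the acceptance script fits the
four scenarios at 2 × 2,000. The full-length study configuration is
exported but not exercised by the tests.

The prior-shrinkage check fits a moderately informative treatment
hyper-prior, Normal(3, 1) — informative relative to the diffuse
normal(0, 10), but wide enough that the posterior median remains
distinguishable from the prior mean — on a dataset large enough that
the data genuinely inform the posterior (10 species, 8 sites). With
very sparse data the hierarchical SD inflates and species effects can
drift past the prior mean, so the interpolation property is a statement
about informative-data regimes, not a theorem for arbitrary data.

## Known limitations

* No data augmentation for never-detected species; richness estimates
  condition on the observed species pool.
* Missing visits are supported (mask-based), but sites and species must
  form a complete factorial otherwise.
* The per-family random-walk sampler is robust but not the fastest
  mixer for strongly correlated coefficient pairs (e.g. persistence vs
  colonization for ubiquitous species); long chains or the replica
  configuration are advised for final inference.
* The informed-prior machinery covers exactly the two hyper-means the
  elicitation design targets (detection intercept, occupancy treatment
  effect); other families always get diffuse hyper-priors.
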