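# msocc — Bayesian multispecies dynamic occupancy modelling

`msocc` fits a hierarchical community occupancy model to repeated
presence/absence survey data — the kind of data produced by multi-year,
multi-visit point-count studies of a breeding bird community — and
derives the community-level summaries ecologists report from such
models: species richness and treatment contrasts, compositional
similarity, turnover, local extinction and survival. It was built to
analyse a randomized salvage-logging experiment (27 species, 24 forest
stands split between control and harvested treatments in two management
districts, 3 years, 3 visits per year) and ships a synthetic-data
generator that reproduces that design with known ground truth, since
the original field data were never deposited.

## The model

For species *i*, site *k*, year *t* and visit *j*:

```
z[i,k,t]   ~ Bernoulli(psi[i,k,t])                    latent occupancy
y[i,k,t,j] ~ Bernoulli(z[i,k,t] * p[i,k,t,j])         detection

logit p          = a0_i + aT_i*TRT_k + aY_{i,t} + aD1_i*date + aD2_i*date^2
logit psi (t=1)  = b0_i + alpha_i*TRT_k + bD_i*DIST_k
logit psi (t>1)  = theta_i*z[i,k,t-1] + theta'_i*(1 - z[i,k,t-1])
                   + alpha_i*TRT_k + bD_i*DIST_k + bTY_{i,t}*TRT_k
```

Occupancy dynamics are autologistic: after the base year the intercept
is `theta'` (colonization scale) when the site was unoccupied the
previous year and `theta` (persistence scale) when it was occupied.
Each species-level coefficient family is drawn from a community normal
distribution, `coef_i ~ Normal(mu_f, sigma_f)`; the hyper-parameters
`(mu_f, sigma_f)` summarise the community response and shrink data-poor
species toward the community mean. The headline quantity is
`mu[occ_treatment]` — the community-level treatment effect on occupancy.

Four hyper-prior scenarios are supported: all-diffuse, informed
detection intercept (a beta prior on the probability scale, fitted by
the method of moments to species-specific posterior means from an
earlier, ecologically similar study), informed occupancy treatment
effect (a fitted normal), and both informed.

Inference is by a Metropolis-within-Gibbs sampler: exact
full-conditional updates of the latent states, vectorised random-walk
Metropolis sweeps over coefficient families with burn-in-only
adaptation, conjugate normal updates of hyper-means, and Metropolis
updates for the beta-informed hyper-mean and the uniform(0, 10)
hyper-SDs. Convergence is assessed with the Gelman–Rubin statistic and
model fit with a posterior predictive check (Freeman–Tukey discrepancy
on species × site detection counts).

## Worked example

The numbered drivers under `analysis/` run the full study:

```
python analysis/01_simulate.py --seed 1
python analysis/02_fit_scenarios.py --seed 1
python analysis/03_diagnose.py --seed 1
python analysis/04_community_summaries.py
```

`01_simulate.py` prints

```
simulated 27 species x 24 sites x 3 years x 3 visits (seed 1)
  1505 detections; true occupancy fraction 0.76
  true treatment hyper-mean 1.00 (logit scale)
wrote results/data.csv and results/truth.csv
```

and `04_community_summaries.py` ends with (numbers from the run above;
2 chains × 3,000 iterations per scenario):

```
treatment hyper-mean (occupancy, logit scale) by prior scenario:
          scenario  posterior_median     ci_lo    ci_hi
           diffuse          0.794561 -0.223125 2.174199
informed_detection          0.864575 -0.141686 2.755675
informed_treatment          0.727824  0.098295 1.378956
     informed_both          0.595943 -0.014622 1.334021

informed-both scenario: 24/27 species with positive treatment effect;
27 intervals contain 0
```

Read: under every prior scenario the community-level treatment effect
on occupancy is positive (harvested stands have higher occupancy on the
logit scale), the informed-treatment prior (elicited mean ≈ 0.43, SD ≈
0.56) pulls the estimate toward itself and tightens the interval, and
every interval covers the simulation truth of 1.0. The per-species
effect tables, richness contrasts (treated minus control, per district
and year), Dice similarity summaries, turnover/extinction and local
survival tables are written under `results/`.

The same pipeline is available as a CLI (`msocc simulate | fit |
diagnose | summarize | run-all`); `msocc run-all --seed 7 --outdir out`
runs all four scenarios end to end and is byte-reproducible for a given
seed.

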