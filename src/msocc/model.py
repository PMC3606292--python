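"""Probability model: likelihood, linear predictors, hierarchical prior.

State layer: occupancy z[i, k, t] ~ Bernoulli(psi[i, k, t]) with

    logit psi (year 1)  = b0_i + alpha_i * TRT_k + bD_i * DIST_k
    logit psi (year t>1) = theta_i * z[i,k,t-1] + theta'_i * (1 - z[i,k,t-1])
                           + alpha_i * TRT_k + bD_i * DIST_k + bTY_{i,t} * TRT_k

so the base-year intercept is replaced for later years by a two-term
autologistic intercept: theta' when the site was unoccupied the
previous year, theta when it was occupied (equivalently
logit psi = theta' + (theta - theta') * z_prev + ...).

Observation layer: detection y[i, k, t, j] ~ Bernoulli(z[i,k,t] * p) with

    logit p = a0_i + aT_i * TRT_k + aY_{i,t} + aD1_i * date + aD2_i * date^2

on the centred/scaled survey date, so a species absent from a site-year
can never be detected there.

Species coefficients in each family are normal draws from community
hyper-parameters (mu_f, sigma_f); the hyper-prior scenario is described
in :mod:`msocc.priors`.

All functions here are pure and evaluable at any parameter state; the
sampler composes them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit

from .data import DetectionData
from .design import StudyDesign
from .families import FamilyLayout, HyperParams, SpeciesParams
from .priors import PriorConfig

#: probabilities are clipped this far from {0, 1} before taking logs
PROB_EPS = 1e-12

_LOG_2PI = float(np.log(2.0 * np.pi))


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


# ---------------------------------------------------------------------------
# linear predictors / probabilities


def detection_eta(params: SpeciesParams, design: StudyDesign) -> np.ndarray:
    """Detection linear predictor, shape (S, K, T, J)."""
    L = params.layout
    v = params.values
    a0 = v[:, L["det_intercept"]][:, None, None, None]
    aT = v[:, L["det_treatment"]][:, None, None, None]
    aD1 = v[:, L["det_date"]][:, None, None, None]
    aD2 = v[:, L["det_date_sq"]][:, None, None, None]
    aY = params.year_offsets("det_year_")[:, None, :, None]
    d = design.date_scaled[None, :, :, :]
    trt = design.treatment[None, :, None, None]
    return a0 + aT * trt + aY + aD1 * d + aD2 * d * d


def detection_prob_array(params: SpeciesParams, design: StudyDesign) -> np.ndarray:
    """Detection probability per (species, site, year, visit)."""
    return expit(detection_eta(params, design))


def detection_prob(params: SpeciesParams, species: int, year: int,
                   treatment: int, date_scaled: float) -> float:
    """Single-cell detection probability (0-based species/year indices)."""
    L = params.layout
    v = params.values[species]
    eta = v[L["det_intercept"]] + v[L["det_treatment"]] * treatment
    if year > 0:
        eta += v[L[f"det_year_{year + 1}"]]
    eta += v[L["det_date"]] * date_scaled + v[L["det_date_sq"]] * date_scaled ** 2
    return float(expit(eta))


def occupancy_eta(params: SpeciesParams, design: StudyDesign,
                  z: np.ndarray) -> np.ndarray:
    """Occupancy linear predictor, shape (S, K, T); years t>1 condition
    on z of the previous year."""
    L = params.layout
    v = params.values
    S, K, T = params.n_species, design.n_sites, design.n_years
    trt = design.treatment[None, :].astype(float)
    dist = design.district[None, :].astype(float)
    base = (v[:, L["occ_treatment"]][:, None] * trt
            + v[:, L["occ_district"]][:, None] * dist)
    eta = np.empty((S, K, T))
    eta[:, :, 0] = v[:, L["occ_intercept"]][:, None] + base
    if T > 1:
        theta = v[:, L["occ_persist"]][:, None]
        theta_p = v[:, L["occ_colonize"]][:, None]
        bTY = params.year_offsets("occ_trt_year_")
        for t in range(1, T):
            zprev = z[:, :, t - 1]
            eta[:, :, t] = (theta * zprev + theta_p * (1.0 - zprev)
                            + base + bTY[:, t][:, None] * trt)
    return eta


def occupancy_prob_array(params: SpeciesParams, design: StudyDesign,
                         z: np.ndarray) -> np.ndarray:
    """Occupancy probability per (species, site, year) given the latent
    history z (only z of the previous year enters)."""
    return expit(occupancy_eta(params, design, z))


def occupancy_prob(params: SpeciesParams, species: int, year: int,
                   treatment: int, district: int,
                   z_prev: int | None = None) -> float:
    """Single-cell occupancy probability (0-based species/year indices).

    ``z_prev`` is the previous year's occupancy state and must be given
    exactly when ``year > 0``.
    """
    L = params.layout
    v = params.values[species]
    if year == 0:
        if z_prev is not None:
            raise ValueError("z_prev must not be supplied for the base year")
        eta = v[L["occ_intercept"]]
    else:
        if z_prev is None:
            raise ValueError("z_prev is required for years after the base year")
        eta = (v[L["occ_persist"]] * z_prev
               + v[L["occ_colonize"]] * (1 - z_prev)
               + v[L[f"occ_trt_year_{year + 1}"]] * treatment)
    eta += v[L["occ_treatment"]] * treatment + v[L["occ_district"]] * district
    return float(expit(eta))


# ---------------------------------------------------------------------------
# likelihood


def detection_loglik_by_species(data: DetectionData, z: np.ndarray,
                                p: np.ndarray) -> np.ndarray:
    """Observation-layer log-likelihood per species, shape (S,).

    Only occupied, surveyed cells contribute (a y=1 at z=0 is handled by
    :func:`log_likelihood`; here it is masked out).
    """
    p = _clip(p)
    mask = data.obs_mask & (z[:, :, :, None] == 1)
    y = data.y
    ll = np.where(mask, y * np.log(p) + (1 - y) * np.log1p(-p), 0.0)
    return ll.sum(axis=(1, 2, 3))


def occupancy_loglik_by_species(z: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """State-layer log-likelihood per species, shape (S,)."""
    psi = _clip(psi)
    ll = z * np.log(psi) + (1 - z) * np.log1p(-psi)
    return ll.sum(axis=(1, 2))


def log_likelihood(data: DetectionData, z: np.ndarray,
                   params: SpeciesParams) -> float:
    """Joint log p(y, z | params). Returns -inf for the impossible event
    of a detection at an unoccupied site-year."""
    z = np.asarray(z)
    if np.any((z == 0) & data.detected_any):
        return -np.inf
    psi = occupancy_prob_array(params, data.design, z)
    p = detection_prob_array(params, data.design)
    return float(occupancy_loglik_by_species(z, psi).sum()
                 + detection_loglik_by_species(data, z, p).sum())


# ---------------------------------------------------------------------------
# prior


def _normal_logpdf(x, mu, sigma):
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def detection_mu_logprior(mu: float, a: float, b: float) -> float:
    """Log hyper-prior density of the detection-intercept hyper-mean.

    The beta(a, b) prior is placed on the probability scale
    m = expit(mu); expressed on the logit scale it picks up the
    Jacobian dm/dmu = m(1-m).
    """
    m = _clip(expit(mu))
    return float((a - 1.0) * np.log(m) + (b - 1.0) * np.log1p(-m)
                 - betaln(a, b) + np.log(m) + np.log1p(-m))


def hyper_logprior(hyper: HyperParams, prior: PriorConfig) -> float:
    """Log density of the hyper-parameters under a prior scenario."""
    L = hyper.layout
    if np.any(hyper.sigma <= 0) or np.any(hyper.sigma >= prior.sigma_upper):
        return -np.inf
    lp = -hyper.layout.n_families * np.log(prior.sigma_upper)  # uniform SDs
    for f, name in enumerate(L.names):
        mu = hyper.mu[f]
        if name == "det_intercept":
            lp += detection_mu_logprior(mu, *prior.beta_params)
        elif name == "occ_treatment":
            lp += _normal_logpdf(mu, *prior.normal_params)
        else:
            lp += _normal_logpdf(mu, 0.0, prior.mu_sd)
    return float(lp)


def species_logprior(params: SpeciesParams, hyper: HyperParams) -> float:
    """Sum of normal log-densities of species coefficients given hypers.
    -inf when any hyper SD is non-positive."""
    if np.any(hyper.sigma <= 0):
        return -np.inf
    return float(_normal_logpdf(params.values, hyper.mu[None, :],
                                hyper.sigma[None, :]).sum())


def log_prior(params: SpeciesParams, hyper: HyperParams,
              prior: PriorConfig) -> float:
    """Log density of species coefficients given hypers, plus the
    scenario's hyper-prior terms. -inf for sigma outside (0, upper)."""
    hp = hyper_logprior(hyper, prior)
    if not np.isfinite(hp):
        return hp
    return float(species_logprior(params, hyper) + hp)
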