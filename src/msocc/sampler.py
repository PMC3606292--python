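"""Metropolis-within-Gibbs posterior simulation.

Update cycle per iteration:

1. Latent occupancy states z: exact full-conditional (Gibbs) draws in a
   systematic sweep over years ascending, vectorised over species and
   sites. Cells with at least one detection are forced to z = 1; the
   conditional for a free cell combines its occupancy prior, the
   probability of the all-zero detection record, and (except in the
   final year) the next year's autologistic state term.
2. Species coefficients: one random-walk Metropolis sweep per
   coefficient family, proposing all species simultaneously (species
   blocks are conditionally independent given the hypers, so per-species
   accept/reject within a family is a valid block update).
3. Hyper-parameters: conjugate normal draws for every hyper-mean with a
   normal hyper-prior; random-walk Metropolis on the logit scale for the
   beta-informed detection-intercept hyper-mean; random-walk Metropolis
   for hyper-SDs restricted to their uniform(0, upper) support.

Proposal scales can adapt toward a 0.44 acceptance rate during burn-in
only (Robbins-Monro), leaving the post-burn-in kernel stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .data import DetectionData
from .families import FamilyLayout, HyperParams, SpeciesParams
from .model import detection_eta, occupancy_eta, detection_mu_logprior
from .priors import PriorConfig

#: target acceptance rate for scalar random-walk proposals
TARGET_ACCEPT = 0.44


@dataclass
class McmcConfig:
    """Chain configuration.

    The original study's settings are 3 chains of 500,000 iterations,
    250,000 burn-in, thin 50 (:data:`STUDY_CONFIG`); the desk-scale
    default used throughout the tests is :data:`DESK_CONFIG`.
    """

    n_chains: int = 3
    n_iter: int = 5_000
    n_burnin: int = 2_500
    thin: int = 5
    seed: int = 0
    proposal_sd: float = 0.3
    adapt: bool = True

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iter < 1:
            raise ValueError("n_chains and n_iter must be >= 1")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must satisfy 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains, "n_iter": self.n_iter,
            "n_burnin": self.n_burnin, "thin": self.thin, "seed": self.seed,
            "proposal_sd": self.proposal_sd, "adapt": self.adapt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "McmcConfig":
        return cls(**d)


#: desk-scale settings for routine runs and tests
DESK_CONFIG = McmcConfig(n_chains=3, n_iter=5_000, n_burnin=2_500, thin=5)
#: the original study's full-length chain settings
STUDY_CONFIG = McmcConfig(n_chains=3, n_iter=500_000, n_burnin=250_000, thin=50)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws from all chains.

    Arrays are indexed (chain, draw, ...): ``species`` is
    (C, D, n_species, n_families), ``mu``/``sigma`` are (C, D,
    n_families) and ``z`` is (C, D, S, K, T).
    """

    layout: FamilyLayout
    species: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    config: McmcConfig
    accept_rate: np.ndarray = None  # (C, n_families) species-update rate

    @property
    def n_chains(self) -> int:
        return self.species.shape[0]

    @property
    def n_draws(self) -> int:
        """Draws per chain."""
        return self.species.shape[1]

    def mu_draws(self, family: str) -> np.ndarray:
        """(C, D) draws of one hyper-mean."""
        return self.mu[:, :, self.layout[family]]

    def sigma_draws(self, family: str) -> np.ndarray:
        return self.sigma[:, :, self.layout[family]]

    def species_draws(self, family: str) -> np.ndarray:
        """(C, D, S) draws of one species-coefficient family."""
        return self.species[:, :, :, self.layout[family]]

    def z_flat(self) -> np.ndarray:
        """(C*D, S, K, T) latent states pooled over chains."""
        return self.z.reshape((-1,) + self.z.shape[2:])

    def scalar_chains(self) -> dict:
        """{name: (C, D)} for every scalar parameter (for diagnostics)."""
        out = {}
        for name in self.layout.names:
            out[f"mu[{name}]"] = self.mu_draws(name)
            out[f"sigma[{name}]"] = self.sigma_draws(name)
        S = self.species.shape[2]
        for name in self.layout.names:
            col = self.layout[name]
            for i in range(S):
                out[f"{name}[{i + 1}]"] = self.species[:, :, i, col]
        return out


# ---------------------------------------------------------------------------
# fast masked log-likelihood kernels
#
# With eta the logit and y binary, log p = -log(1 + e^-eta) and
# log(1 - p) = log p - eta, so each Bernoulli term is logp - (1-y)*eta.


def _det_ll_by_species(eta, zmask, one_minus_y):
    logp = -np.logaddexp(0.0, -eta)
    return np.where(zmask, logp - one_minus_y * eta, 0.0).sum(axis=(1, 2, 3))


def _occ_ll_by_species(eta, z):
    logpsi = -np.logaddexp(0.0, -eta)
    return (logpsi - (1 - z) * eta).sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# latent-state update


def _missed_detection_ll(data: DetectionData, params: SpeciesParams) -> np.ndarray:
    """(S, K, T) log-probability of an all-zero detection record given
    occupancy (sum over observed visits of log(1 - p))."""
    eta_p = detection_eta(params, data.design)
    log1mp = -np.logaddexp(0.0, eta_p)
    return np.where(data.obs_mask, log1mp, 0.0).sum(axis=3)


def z_conditional_prob(data: DetectionData, params: SpeciesParams,
                       z: np.ndarray, t: int,
                       miss_ll: np.ndarray | None = None) -> np.ndarray:
    """P(z[., ., t] = 1 | everything else), shape (S, K).

    Exact full conditional: proportional to the year-t occupancy term
    (conditional on z at t-1), the detection record of year t, and —
    when year t+1 exists — the autologistic term of year t+1 evaluated
    at both candidate states. Cells with a detection have probability 1.
    """
    design = data.design
    L = params.layout
    v = params.values
    T = design.n_years
    if miss_ll is None:
        miss_ll = _missed_detection_ll(data, params)
    miss_ll_t = miss_ll[:, :, t]

    eta_t = occupancy_eta(params, design, z)[:, :, t]
    lq1 = -np.logaddexp(0.0, -eta_t) + miss_ll_t
    lq0 = -np.logaddexp(0.0, eta_t)
    if t < T - 1:
        trt = design.treatment[None, :].astype(float)
        dist = design.district[None, :].astype(float)
        base = (v[:, L["occ_treatment"]][:, None] * trt
                + v[:, L["occ_district"]][:, None] * dist
                + params.year_offsets("occ_trt_year_")[:, t + 1][:, None] * trt)
        eta1 = v[:, L["occ_persist"]][:, None] + base
        eta0 = v[:, L["occ_colonize"]][:, None] + base
        znext = z[:, :, t + 1]
        # Bernoulli(z_next; psi_next(z_t)) for each candidate z_t
        lq1 += -np.logaddexp(0.0, -eta1) - (1 - znext) * eta1
        lq0 += -np.logaddexp(0.0, -eta0) - (1 - znext) * eta0
    with np.errstate(over="ignore"):  # exp overflow -> prob 0, correct limit
        prob = 1.0 / (1.0 + np.exp(lq0 - lq1))
    return np.where(data.detected_any[:, :, t], 1.0, prob)


def update_z(data: DetectionData, params: SpeciesParams, z: np.ndarray,
             rng) -> np.ndarray:
    """One systematic Gibbs sweep over years (ascending) of the latent
    occupancy states; returns a new array."""
    rng = as_rng(rng)
    z = np.array(z, dtype=np.int8, copy=True)
    miss_ll = _missed_detection_ll(data, params)  # z-independent, reusable
    for t in range(data.design.n_years):
        p1 = z_conditional_prob(data, params, z, t, miss_ll=miss_ll)
        z[:, :, t] = rng.random(p1.shape) < p1
    return z


# ---------------------------------------------------------------------------
# species-coefficient update


def update_species_params(data: DetectionData, z: np.ndarray,
                          params: SpeciesParams, hyper: HyperParams,
                          rng, proposal_sd=0.3):
    """One random-walk Metropolis sweep over coefficient families.

    Each family proposes all species jointly and accepts per species
    using that species' likelihood change plus its community-normal
    prior term. Returns ``(new_params, accept_fraction_per_family)``.
    """
    rng = as_rng(rng)
    design = data.design
    L = params.layout
    S, F = params.n_species, L.n_families
    sd = np.broadcast_to(np.asarray(proposal_sd, dtype=float), (F,))
    params = params.copy()
    zmask = data.obs_mask & (z[:, :, :, None] == 1)
    one_minus_y = (1 - data.y).astype(float)
    det_ll = _det_ll_by_species(detection_eta(params, design), zmask, one_minus_y)
    occ_ll = _occ_ll_by_species(occupancy_eta(params, design, z), z)
    accept = np.zeros(F)
    for f, name in enumerate(L.names):
        old = params.values[:, f].copy()
        prop = old + sd[f] * rng.standard_normal(S)
        params.values[:, f] = prop
        if L.is_detection(name):
            new_ll = _det_ll_by_species(detection_eta(params, design),
                                        zmask, one_minus_y)
            cur_ll = det_ll
        else:
            new_ll = _occ_ll_by_species(occupancy_eta(params, design, z), z)
            cur_ll = occ_ll
        mu_f, s_f = hyper.mu[f], hyper.sigma[f]
        d_prior = 0.5 * (((old - mu_f) / s_f) ** 2 - ((prop - mu_f) / s_f) ** 2)
        log_r = new_ll - cur_ll + d_prior
        acc = np.log(rng.random(S)) < log_r
        params.values[:, f] = np.where(acc, prop, old)
        mixed_ll = np.where(acc, new_ll, cur_ll)
        if L.is_detection(name):
            det_ll = mixed_ll
        else:
            occ_ll = mixed_ll
        accept[f] = acc.mean()
    return params, accept


# ---------------------------------------------------------------------------
# hyper-parameter update


def mu_conjugate_moments(values: np.ndarray, sigma: float,
                         prior_mean: float, prior_sd: float):
    """Posterior (mean, sd) of a normal hyper-mean given species values
    with known community SD ``sigma`` and a normal(prior_mean, prior_sd)
    hyper-prior."""
    values = np.asarray(values, dtype=float)
    n = values.size
    prec = n / sigma ** 2 + 1.0 / prior_sd ** 2
    mean = (values.sum() / sigma ** 2 + prior_mean / prior_sd ** 2) / prec
    return mean, 1.0 / np.sqrt(prec)


def update_hyper(params: SpeciesParams, hyper: HyperParams,
                 prior: PriorConfig, rng, mu_det_sd: float = 0.3,
                 sigma_sd=0.2):
    """One update of all hyper-parameters.

    Normal-prior hyper-means are drawn from their conjugate normal full
    conditionals; the detection-intercept hyper-mean (beta prior on the
    probability scale) and all hyper-SDs use random-walk Metropolis.
    Returns ``(new_hyper, mu_det_accepted, sigma_accept_mask)``.
    """
    rng = as_rng(rng)
    L = hyper.layout
    F = L.n_families
    S = params.n_species
    hyper = hyper.copy()
    x = params.values  # (S, F)

    # conjugate means
    prior_mean = np.zeros(F)
    prior_sd = np.full(F, prior.mu_sd)
    i_trt = L["occ_treatment"]
    prior_mean[i_trt], prior_sd[i_trt] = prior.normal_params
    prec = S / hyper.sigma ** 2 + 1.0 / prior_sd ** 2
    mean = (x.sum(axis=0) / hyper.sigma ** 2 + prior_mean / prior_sd ** 2) / prec
    new_mu = rng.normal(mean, 1.0 / np.sqrt(prec))

    # detection-intercept hyper-mean: Metropolis with beta prior
    i_det = L["det_intercept"]
    a, b = prior.beta_params
    cur = hyper.mu[i_det]
    prop = cur + mu_det_sd * rng.standard_normal()
    s2 = hyper.sigma[i_det] ** 2
    xd = x[:, i_det]
    log_r = (-0.5 * np.sum((xd - prop) ** 2) / s2
             + 0.5 * np.sum((xd - cur) ** 2) / s2
             + detection_mu_logprior(prop, a, b)
             - detection_mu_logprior(cur, a, b))
    mu_det_acc = np.log(rng.random()) < log_r
    new_mu[i_det] = prop if mu_det_acc else cur
    hyper.mu = new_mu

    # hyper-SDs: Metropolis on uniform(0, upper) support
    sig_sd = np.broadcast_to(np.asarray(sigma_sd, dtype=float), (F,))
    cur_sig = hyper.sigma
    prop_sig = cur_sig + sig_sd * rng.standard_normal(F)
    valid = (prop_sig > 0) & (prop_sig < prior.sigma_upper)
    ssq = ((x - hyper.mu[None, :]) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = (-S * np.log(prop_sig / cur_sig)
                 - 0.5 * ssq * (1.0 / prop_sig ** 2 - 1.0 / cur_sig ** 2))
    acc = valid & (np.log(rng.random(F)) < np.where(valid, log_r, -np.inf))
    hyper.sigma = np.where(acc, prop_sig, cur_sig)
    return hyper, mu_det_acc, acc


# ---------------------------------------------------------------------------
# driver


def _init_state(data: DetectionData, layout: FamilyLayout,
                hyper0: HyperParams, rng):
    """Initial (params, z): z forced to 1 where detected, Bernoulli(0.5)
    elsewhere; species coefficients dispersed around the initial hypers."""
    S = data.n_species
    z = np.where(data.detected_any, 1,
                 rng.random(data.detected_any.shape) < 0.5).astype(np.int8)
    vals = rng.normal(hyper0.mu[None, :],
                      np.minimum(hyper0.sigma, 0.5)[None, :],
                      size=(S, layout.n_families))
    return SpeciesParams(layout, vals), z


def run_mcmc(data: DetectionData, prior: PriorConfig | None = None,
             config: McmcConfig | None = None,
             fixed_hyper: HyperParams | None = None,
             progress=None) -> PosteriorDraws:
    """Run the full Metropolis-within-Gibbs sampler.

    Chains use independent substreams spawned from ``config.seed``, so
    the result is a deterministic function of (data, prior, config).
    ``fixed_hyper`` freezes the hyper-parameters at the given values
    (used by the small-scale posterior-correctness oracles); otherwise
    they are sampled under ``prior``.

    Non-convergence is not an error; assess it with
    :mod:`msocc.diagnostics`.
    """
    prior = prior or PriorConfig()
    config = config or DESK_CONFIG
    layout = FamilyLayout(data.design.n_years)
    C, D, F, S = config.n_chains, config.n_saved, layout.n_families, data.n_species
    K, T = data.design.n_sites, data.design.n_years

    out = PosteriorDraws(
        layout=layout,
        species=np.empty((C, D, S, F)),
        mu=np.empty((C, D, F)),
        sigma=np.empty((C, D, F)),
        z=np.empty((C, D, S, K, T), dtype=np.uint8),
        config=config,
        accept_rate=np.zeros((C, F)),
    )
    chain_seeds = np.random.SeedSequence(config.seed).spawn(C)
    batch = 50  # adaptation batch length (burn-in only)
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        if fixed_hyper is not None:
            hyper = fixed_hyper.copy()
        else:
            hyper = HyperParams(layout, np.zeros(F), np.ones(F))
        params, z = _init_state(data, layout, hyper, rng)
        log_sd = np.full(F, np.log(config.proposal_sd))
        log_sig_sd = np.full(F, np.log(0.2))
        log_mudet_sd = np.log(0.3)
        acc_accum = np.zeros(F)
        sig_accum = np.zeros(F)
        mudet_accum = 0.0
        n_kept = 0
        total_acc = np.zeros(F)
        for it in range(config.n_iter):
            z = update_z(data, params, z, rng)
            params, acc = update_species_params(
                data, z, params, hyper, rng, np.exp(log_sd))
            if fixed_hyper is None:
                hyper, mudet_acc, sig_acc = update_hyper(
                    params, hyper, prior, rng,
                    mu_det_sd=np.exp(log_mudet_sd),
                    sigma_sd=np.exp(log_sig_sd))
                sig_accum += sig_acc
                mudet_accum += mudet_acc
            acc_accum += acc
            if it >= config.n_burnin:
                total_acc += acc
            if config.adapt and it < config.n_burnin and (it + 1) % batch == 0:
                delta = min(0.05, 1.0 / np.sqrt((it + 1) / batch))
                log_sd += np.where(acc_accum / batch > TARGET_ACCEPT,
                                   delta, -delta)
                log_sig_sd += np.where(sig_accum / batch > TARGET_ACCEPT,
                                       delta, -delta)
                log_mudet_sd += (delta if mudet_accum / batch > TARGET_ACCEPT
                                 else -delta)
                acc_accum[:] = 0.0
                sig_accum[:] = 0.0
                mudet_accum = 0.0
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                out.species[c, n_kept] = params.values
                out.mu[c, n_kept] = hyper.mu
                out.sigma[c, n_kept] = hyper.sigma
                out.z[c, n_kept] = z
                n_kept += 1
            if progress is not None and (it + 1) % 1000 == 0:
                progress(c, it + 1, config.n_iter)
        out.accept_rate[c] = total_acc / max(config.n_iter - config.n_burnin, 1)
    return out
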