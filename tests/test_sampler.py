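"""Sampler tests: exact latent-state conditionals, Metropolis updates
against independent hand/brute-force computations, conjugate hyper
updates, and the determinism contract."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest, norm

from msocc import (
    DetectionData,
    FamilyLayout,
    HyperParams,
    McmcConfig,
    PriorConfig,
    SpeciesParams,
    StudyDesign,
    log_likelihood,
    run_mcmc,
)
from msocc.sampler import (
    mu_conjugate_moments,
    update_hyper,
    update_species_params,
    update_z,
    z_conditional_prob,
)

from conftest import toy_data, toy_design


class ScriptedRng:
    """Deterministic Generator stand-in: fixed normal and uniform draws."""

    def __init__(self, normal=1.0, uniform=0.5):
        self._n, self._u = normal, uniform

    def standard_normal(self, size=None):
        return np.full(size, self._n) if size is not None else self._n

    def random(self, size=None):
        return np.full(size, self._u) if size is not None else self._u

    def normal(self, loc, scale, size=None):
        return np.asarray(loc) + np.asarray(scale) * self.standard_normal(size)


class TestUpdateZ:
    def test_detections_force_occupancy(self):
        design = toy_design(n_species=1, n_sites=2, n_years=2)
        y = np.zeros((1, 2, 2, 3), int)
        y[0, 0, 0, 1] = 1
        data = toy_data(design, y=y)
        params = SpeciesParams.zeros(FamilyLayout(2), 1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = update_z(data, params, np.ones((1, 2, 2), np.int8), rng)
            assert z[0, 0, 0] == 1

    def test_final_year_conditional_hand_value(self):
        """psi = 0.5, p = 0.5, 3 missed visits:
        P(z=1) = 0.5*0.125 / (0.5*0.125 + 0.5) = 1/9."""
        design = toy_design(n_species=1, n_sites=1, n_years=1, n_visits=3)
        data = toy_data(design)
        params = SpeciesParams.zeros(FamilyLayout(1), 1)
        prob = z_conditional_prob(data, params, np.zeros((1, 1, 1), np.int8), 0)
        assert prob[0, 0] == pytest.approx(1.0 / 9.0, abs=1e-12)

    @pytest.mark.parametrize("z_next", [0, 1])
    def test_nonfinal_year_conditional_matches_enumeration(self, z_next):
        """Exhaustive enumeration oracle on a 1-species, 1-site, 2-year toy
        with all-zero detection history."""
        design = toy_design(n_species=1, n_sites=1, n_years=2, n_visits=3)
        data = toy_data(design)
        params = SpeciesParams.from_dict(
            FamilyLayout(2), 1, det_intercept=-0.4, occ_intercept=0.3,
            occ_persist=1.2, occ_colonize=-0.8)
        p, psi1 = expit(-0.4), expit(0.3)

        def joint(z1, z2):
            psi2 = expit(1.2) if z1 else expit(-0.8)
            return ((psi1 if z1 else 1 - psi1) * (1 - p) ** (3 * z1)
                    * (psi2 if z2 else 1 - psi2) * (1 - p) ** (3 * z2))

        want = joint(1, z_next) / (joint(1, z_next) + joint(0, z_next))
        z = np.array([[[0, z_next]]], dtype=np.int8)
        got = z_conditional_prob(data, params, z, 0)[0, 0]
        assert got == pytest.approx(want, abs=1e-12)


class TestUpdateSpeciesParams:
    def test_degenerate_proposal_stays_put(self):
        design = toy_design(n_species=2, n_sites=3, n_years=2)
        data = toy_data(design)
        layout = FamilyLayout(2)
        params = SpeciesParams(layout, np.random.default_rng(0).normal(
            size=(2, layout.n_families)))
        hyper = HyperParams.from_dicts(layout, mu=0.0, sigma=1.0)
        z = np.zeros((2, 3, 2), np.int8)
        new, _ = update_species_params(data, z, params, hyper,
                                       np.random.default_rng(1), 1e-14)
        assert np.allclose(new.values, params.values, atol=1e-10)

    def test_flat_likelihood_samples_the_prior(self):
        """With no sites the stationary distribution is the community
        normal prior (KS test on thinned sweeps)."""
        design = StudyDesign(n_species=1, treatment=np.zeros(0, int),
                             district=np.zeros(0, int),
                             date_raw=np.zeros((0, 1, 2)))
        data = DetectionData(y=np.zeros((1, 0, 1, 2), int), design=design)
        layout = FamilyLayout(1)
        hyper = HyperParams.from_dicts(layout, mu={"*": 0.7}, sigma={"*": 0.6})
        params = SpeciesParams.from_dict(layout, 1,
                                         **{n: 0.7 for n in layout.names})
        rng = np.random.default_rng(12)
        z = np.zeros((1, 0, 1), np.int8)
        kept = []
        for sweep in range(10_000):
            params, _ = update_species_params(data, z, params, hyper, rng, 1.0)
            if sweep % 10 == 9:
                kept.append(params.values[0, layout["occ_intercept"]])
        stat = kstest(np.asarray(kept), norm(0.7, 0.6).cdf)
        assert stat.pvalue > 0.01

    def test_acceptance_decisions_match_independent_computation(self):
        """Drive one sweep with scripted proposals/uniforms and reproduce
        every accept/reject decision from the joint density evaluated with
        the standalone model functions."""
        design = toy_design(n_species=1, n_sites=2, n_years=2, n_visits=2,
                            treatment=[0, 1], district=[0, 1])
        y = np.zeros((1, 2, 2, 2), int)
        y[0, 0, 0, 0] = 1
        y[0, 1, 1, 1] = 1
        data = toy_data(design, y=y)
        layout = FamilyLayout(2)
        hyper = HyperParams.from_dicts(layout, mu={"*": 0.2}, sigma={"*": 0.8})
        start = SpeciesParams.from_dict(layout, 1,
                                        **{n: 0.1 for n in layout.names})
        z = np.ones((1, 2, 2), np.int8)
        sd, u = 0.5, 0.62
        rng = ScriptedRng(normal=1.0, uniform=u)
        got, _ = update_species_params(data, z, start, hyper, rng, sd)

        expect = start.copy()
        for f, name in enumerate(layout.names):
            prop = expect.copy()
            prop.values[0, f] += sd * 1.0
            log_r = (log_likelihood(data, z, prop)
                     - log_likelihood(data, z, expect)
                     + norm(0.2, 0.8).logpdf(prop.values[0, f])
                     - norm(0.2, 0.8).logpdf(expect.values[0, f]))
            if np.log(u) < log_r:
                expect = prop
        assert np.allclose(got.values, expect.values)


class TestUpdateHyper:
    def test_conjugate_moments_formula(self):
        x = np.array([0.2, 1.0, -0.3, 0.7])
        mean, sd = mu_conjugate_moments(x, sigma=0.5, prior_mean=1.0,
                                        prior_sd=2.0)
        prec = 4 / 0.25 + 1 / 4.0
        want_mean = (x.sum() / 0.25 + 1.0 / 4.0) / prec
        assert mean == pytest.approx(want_mean)
        assert sd == pytest.approx(1 / np.sqrt(prec))

    def test_vague_prior_recovers_sample_mean(self):
        x = np.array([0.2, 1.0, -0.3, 0.7])
        mean, _ = mu_conjugate_moments(x, sigma=0.5, prior_mean=0.0,
                                       prior_sd=1e9)
        assert mean == pytest.approx(x.mean(), abs=1e-6)

    def test_identical_species_concentrate_posterior(self):
        layout = FamilyLayout(1)
        params = SpeciesParams.from_dict(layout, 20,
                                         **{n: 1.3 for n in layout.names})
        hyper = HyperParams.from_dicts(layout, mu=0.0, sigma=0.01)
        rng = np.random.default_rng(3)
        for _ in range(20):
            hyper, _, _ = update_hyper(params, hyper, PriorConfig(), rng)
        f = layout["occ_district"]
        assert abs(hyper.mu[f] - 1.3) < 0.05

    def test_sigma_stays_in_uniform_support(self):
        layout = FamilyLayout(1)
        params = SpeciesParams(layout, np.random.default_rng(0).normal(
            0, 3, size=(10, layout.n_families)))
        hyper = HyperParams.from_dicts(layout, mu=0.0, sigma=9.9)
        rng = np.random.default_rng(4)
        for _ in range(200):
            hyper, _, _ = update_hyper(params, hyper, PriorConfig(), rng,
                                       sigma_sd=5.0)
            assert np.all(hyper.sigma > 0) and np.all(hyper.sigma < 10.0)


class TestRunMcmc:
    def test_bit_identical_under_same_seed(self):
        from msocc import simulate_dataset
        data, _ = simulate_dataset(seed=2, n_species=3, n_sites_per_cell=1,
                                   n_years=2, n_visits=2)
        cfg = McmcConfig(n_chains=2, n_iter=60, n_burnin=20, thin=2, seed=11)
        a = run_mcmc(data, PriorConfig(), cfg)
        b = run_mcmc(data, PriorConfig(), cfg)
        assert np.array_equal(a.species, b.species)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.z, b.z)

    @pytest.mark.parametrize("kw", [
        dict(n_burnin=100, n_iter=100),
        dict(n_burnin=200, n_iter=100),
        dict(thin=0),
        dict(n_chains=0),
        dict(proposal_sd=0.0),
    ])
    def test_invalid_config_rejected(self, kw):
        base = dict(n_chains=1, n_iter=100, n_burnin=50, thin=1)
        base.update(kw)
        with pytest.raises(ValueError):
            McmcConfig(**base)

    def test_stored_z_respects_forced_occupancy(self, small_fit):
        data, _, draws = small_fit
        forced = data.detected_any[None, None]
        assert np.all(draws.z[np.broadcast_to(forced, draws.z.shape)] == 1)

    def test_every_family_mixes(self, small_fit):
        """Post burn-in, every coefficient family both accepts and rejects
        proposals (no frozen or runaway coordinates)."""
        _, _, draws = small_fit
        assert np.all(draws.accept_rate > 0.0)
        assert np.all(draws.accept_rate < 1.0)
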