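"""Derived-statistic tests: hand examples, brute-force oracle
equivalence on random latent arrays, and structural identities."""

import numpy as np
import pytest

from msocc import make_design
from msocc.stats import (
    effect_table,
    extinction,
    local_survival,
    local_survival_draws,
    richness,
    richness_contrasts,
    richness_draws,
    similarity,
    similarity_draws,
    turnover,
)


def z_single(arr):
    """(S, K, T) array from a nested list."""
    return np.asarray(arr, dtype=int)


class TestRichness:
    def test_saturated_and_empty(self):
        z = np.ones((27, 2, 1), int)
        assert richness(z, 0, 0) == 27
        assert richness(np.zeros((27, 2, 1), int), 1, 0) == 0

    def test_hand_count(self):
        z = z_single([[[1]], [[0]], [[1]], [[1]], [[0]]])
        assert richness(z, 0, 0) == 3


class TestSimilarity:
    def base(self, za, zb):
        S = len(za)
        z = np.zeros((S, 2, 1), int)
        z[:, 0, 0], z[:, 1, 0] = za, zb
        return z

    def test_identical_nonempty(self):
        z = self.base([1, 1, 0], [1, 1, 0])
        assert similarity(z, 0, 1, 0) == 1.0

    def test_disjoint(self):
        z = self.base([1, 0, 1, 0], [0, 1, 0, 1])
        assert similarity(z, 0, 1, 0) == 0.0

    def test_hand_dice(self):
        # A={1,2,3}, B={2,3,4,5} -> 2*2/(3+4) = 4/7
        z = self.base([1, 1, 1, 0, 0], [0, 1, 1, 1, 1])
        assert similarity(z, 0, 1, 0) == pytest.approx(4 / 7)
        assert similarity(z, 0, 1, 0, method="jaccard") == pytest.approx(2 / 5)

    def test_both_empty_is_missing(self):
        z = self.base([0, 0], [0, 0])
        assert np.isnan(similarity(z, 0, 1, 0))

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        z = (rng.random((8, 4, 1)) < 0.5).astype(int)
        for a in range(4):
            for b in range(a + 1, 4):
                assert similarity(z, a, b, 0) == similarity(z, b, a, 0)

    def test_nested_sets_closed_form(self):
        # A subset of B: Dice = 2|A| / (|A| + |B|)
        z = self.base([1, 1, 0, 0, 0], [1, 1, 1, 1, 0])
        assert similarity(z, 0, 1, 0) == pytest.approx(2 * 2 / (2 + 4))

    def test_distinct_sites_required(self):
        z = self.base([1], [1])
        with pytest.raises(ValueError):
            similarity(z, 0, 0, 0)


class TestTurnoverExtinction:
    def two_year(self, before, now):
        S = len(before)
        z = np.zeros((S, 1, 2), int)
        z[:, 0, 0], z[:, 0, 1] = before, now
        return z

    def test_turnover_bounds_and_hand(self):
        assert turnover(self.two_year([1, 1, 0], [1, 1, 0]), 0, 1) == 0.0
        assert turnover(self.two_year([1, 1, 0, 0], [0, 0, 1, 1]), 0, 1) == 1.0
        # present now {1,2,3}, before {2,3,4} -> 1/3
        assert turnover(self.two_year([0, 1, 1, 1], [1, 1, 1, 0]), 0, 1) == (
            pytest.approx(1 / 3))
        assert np.isnan(turnover(self.two_year([1, 0], [0, 0]), 0, 1))

    def test_extinction_bounds_and_hand(self):
        assert extinction(self.two_year([1, 1], [1, 1]), 0, 0) == 0.0
        assert extinction(self.two_year([1, 1], [0, 0]), 0, 0) == 1.0
        # occupied {1,2,3,4}, next {1,2} -> 0.5
        assert extinction(self.two_year([1, 1, 1, 1], [1, 1, 0, 0]), 0, 0) == 0.5
        assert np.isnan(extinction(self.two_year([0, 0], [1, 0]), 0, 0))

    def test_year_bounds_validated(self):
        z = self.two_year([1], [1])
        with pytest.raises(ValueError):
            turnover(z, 0, 0)
        with pytest.raises(ValueError):
            extinction(z, 0, 1)


class TestLocalSurvival:
    def test_bounds_and_hand(self):
        z = np.ones((1, 2, 3), int)
        assert local_survival_draws(z[None], 0)[0] == 1.0
        z[:, :, 1:] = 0
        assert local_survival_draws(z[None], 0)[0] == 0.0
        # occupied 4 site-years (pre-final), persisted in 3 -> 0.75
        z = np.array([[[1, 1, 1], [1, 1, 0]]])  # (species=1, sites=2, years=3)
        assert local_survival_draws(z[None], 0)[0] == pytest.approx(0.75)

    def test_survival_extinction_complement_identity(self):
        """Per draw and species, pooled survival + pooled extinction
        fraction = 1 on the same pooling."""
        rng = np.random.default_rng(1)
        z = (rng.random((20, 6, 4, 3)) < 0.6).astype(int)
        for i in range(6):
            surv = local_survival_draws(z, i)
            now, nxt = z[:, i, :, :-1], z[:, i, :, 1:]
            occ = now.sum(axis=(1, 2))
            ext = np.where(occ > 0,
                           (now * (1 - nxt)).sum(axis=(1, 2)) / occ, np.nan)
            valid = ~np.isnan(surv)
            assert np.allclose(surv[valid] + ext[valid], 1.0)

    def test_needs_two_years(self):
        with pytest.raises(ValueError):
            local_survival(np.ones((2, 3, 2, 1), int))


class TestRichnessContrasts:
    def test_symmetry_gives_zero(self):
        design = make_design(5, 2, 2, 2, seed=0)
        z = np.ones((3, 5, design.n_sites, 2), int)  # identical sites
        table = richness_contrasts(z, design)
        assert (table["median"] == 0).all()
        assert len(table) == 4  # 2 districts x 2 years

    def test_hand_single_draw(self):
        design = make_design(5, 1, 1, 1, seed=0)
        # one district has sites [control, treated], the other too
        z = np.zeros((1, 5, 4, 1), int)
        for k in range(4):
            n = 3 if design.treatment[k] == 1 else 1
            z[0, :n, k, 0] = 1
        table = richness_contrasts(z, design)
        assert np.allclose(table["median"], 2.0)

    def test_six_rows_for_study_design(self):
        design = make_design(27, 6, 3, 3, seed=1)
        z = (np.random.default_rng(0).random((4, 27, 24, 3)) < 0.5).astype(int)
        table = richness_contrasts(z, design)
        assert len(table) == 6
        assert sorted(table["district"].unique()) == [1, 2]

    def test_empty_cell_flagged(self):
        design = make_design(3, 1, 1, 1, seed=0)
        design.treatment[:] = 0  # no treated sites anywhere
        z = np.ones((1, 3, 4, 1), int)
        with pytest.raises(ValueError, match="contrast undefined"):
            richness_contrasts(z, design)


class TestEffectTable:
    class FakeDraws:
        """Minimal draws object exposing one family."""

        def __init__(self, species, mu):
            self._sp, self._mu = species, mu

        def species_draws(self, family):
            return self._sp

        def mu_draws(self, family):
            return self._mu

    def test_constant_draws(self):
        sp = np.full((2, 10, 3), 1.5)
        t = effect_table(self.FakeDraws(sp, np.full((2, 10), 1.5)), "x")
        assert (t["median"] == 1.5).all()
        assert (t["lo"] == 1.5).all() and (t["hi"] == 1.5).all()
        assert not t["contains_zero"].any()

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(7)
        sp = rng.standard_normal((1, 100_000, 1))
        t = effect_table(self.FakeDraws(sp, sp[:, :, 0]), "x")
        row = t[t["species"] == "sp1"].iloc[0]
        assert abs(row["median"]) < 0.02
        assert row["lo"] == pytest.approx(-1.96, abs=0.05)
        assert row["hi"] == pytest.approx(1.96, abs=0.05)
        assert row["contains_zero"]


def brute_force_all_stats(z, design):
    """Independent nested-loop recomputation of every summary statistic
    for a single draw."""
    S, K, T = z.shape
    rich = np.zeros((K, T), int)
    for k in range(K):
        for t in range(T):
            rich[k, t] = sum(z[i, k, t] for i in range(S))
    sims = {}
    for a in range(K):
        for b in range(a + 1, K):
            for t in range(T):
                both = sum(z[i, a, t] and z[i, b, t] for i in range(S))
                tot = rich[a, t] + rich[b, t]
                sims[(a, b, t)] = 2 * both / tot if tot else np.nan
    tov = {}
    ext = {}
    for k in range(K):
        for t in range(1, T):
            num = sum(z[i, k, t] and not z[i, k, t - 1] for i in range(S))
            tov[(k, t)] = num / rich[k, t] if rich[k, t] else np.nan
        for t in range(T - 1):
            num = sum(z[i, k, t] and not z[i, k, t + 1] for i in range(S))
            ext[(k, t)] = num / rich[k, t] if rich[k, t] else np.nan
    surv = {}
    for i in range(S):
        occ = pers = 0
        for k in range(K):
            for t in range(T - 1):
                if z[i, k, t]:
                    occ += 1
                    pers += z[i, k, t + 1]
        surv[i] = pers / occ if occ else np.nan
    return rich, sims, tov, ext, surv


def test_brute_force_oracle_equivalence():
    """Vectorised statistics agree exactly with nested-loop recomputation
    on random small latent arrays."""
    rng = np.random.default_rng(42)
    design = make_design(6, 1, 3, 2, seed=0)
    for rep in range(25):
        z = (rng.random((6, 4, 3)) < rng.uniform(0.2, 0.8)).astype(int)
        rich, sims, tov, ext, surv = brute_force_all_stats(z, design)
        assert np.array_equal(richness_draws(z)[0], rich)
        for (a, b, t), want in sims.items():
            got = similarity_draws(z, a, b, t)[0]
            assert (np.isnan(got) and np.isnan(want)) or got == want
        for (k, t), want in tov.items():
            got = turnover(z, k, t)
            assert (np.isnan(got) and np.isnan(want)) or got == want
        for (k, t), want in ext.items():
            got = extinction(z, k, t)
            assert (np.isnan(got) and np.isnan(want)) or got == want
        for i, want in surv.items():
            got = local_survival_draws(z, i)[0]
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)
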