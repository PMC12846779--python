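"""Population groups, poverty overlay, wealth distributions, Mann-Whitney."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from hybridcoast.equity import (PopulationGroups, group_masks, mann_whitney,
                                poverty_table, wealth_distribution,
                                weighted_sample)
from hybridcoast.errors import ParameterError


class TestGroupMasks:
    def _extent(self, mask):
        class E:
            flooded = np.asarray(mask, bool)
        return E()

    def test_hand_drawn_masks_on_toy_grid(self):
        pop = np.zeros((4, 4))
        pop[0, :] = 5.0          # populated coastal strip
        pop[3, 3] = 2.0          # populated inland cell
        prone = np.zeros((4, 4), bool)
        prone[0, :2] = True      # two flooded coastal cells
        catch = np.full((4, 4), -1)
        catch[0, 0] = 3          # flooded via transect 3 (benefiting)
        catch[0, 1] = 5          # flooded via transect 5 (no benefit)
        g = group_masks(self._extent(prone), [3], catch, pop)
        assert g.flood_prone.sum() == 2
        assert g.benefit.sum() == 1 and g.benefit[0, 0]
        assert g.outside.sum() == 3  # two dry coastal cells + inland cell

    def test_no_restorable_transects_empty_benefit_group(self):
        pop = np.ones((3, 3))
        prone = np.ones((3, 3), bool)
        g = group_masks(self._extent(prone), [], np.zeros((3, 3), int), pop)
        assert not g.benefit.any()

    def test_all_dry_puts_everyone_outside(self):
        pop = np.ones((3, 3))
        g = group_masks(self._extent(np.zeros((3, 3), bool)), [1],
                        np.full((3, 3), -1), pop)
        assert not g.flood_prone.any()
        assert g.outside.sum() == 9

    def test_subset_invariant_enforced(self):
        with pytest.raises(ParameterError):
            PopulationGroups(outside=np.array([[False]]),
                             flood_prone=np.array([[False]]),
                             benefit=np.array([[True]]))


class TestPovertyTable:
    def _groups(self, shape):
        full = np.ones(shape, bool)
        return PopulationGroups(outside=np.zeros(shape, bool),
                                flood_prone=full, benefit=full.copy())

    def test_uniform_poverty_invariant_to_masking(self):
        pop = np.array([[10.0, 20.0, 30.0]])
        tbl = poverty_table(pop, np.full((1, 3), 0.5), self._groups((1, 3)))
        got = tbl.dropna(subset=["pct_poor"])
        assert np.allclose(got.pct_poor, 50.0)

    def test_certain_poverty_everyone_poor(self):
        pop = np.array([[10.0, 20.0]])
        tbl = poverty_table(pop, np.ones((1, 2)), self._groups((1, 2)))
        assert np.allclose(tbl.dropna(subset=["pct_poor"]).pct_poor, 100.0)

    def test_three_cell_hand_sum(self):
        pop = np.array([[10.0, 20.0, 30.0]])
        p = np.array([[0.1, 0.5, 0.9]])
        tbl = poverty_table(pop, p, self._groups((1, 3)))
        row = tbl[(tbl.group == "flood_prone") & (tbl.year == "present")]
        assert row.poor.iloc[0] == pytest.approx(38.0)
        assert row.pct_poor.iloc[0] == pytest.approx(38.0 / 60.0 * 100.0)

    def test_2050_scales_population_not_poverty(self):
        pop = np.array([[10.0, 20.0, 30.0]])
        p = np.array([[0.1, 0.5, 0.9]])
        tbl = poverty_table(pop, p, self._groups((1, 3)), growth_to_2050=1.5)
        now = tbl[(tbl.group == "benefit") & (tbl.year == "present")]
        fut = tbl[(tbl.group == "benefit") & (tbl.year == 2050)]
        assert fut.total.iloc[0] == pytest.approx(1.5 * now.total.iloc[0])
        assert fut.pct_poor.iloc[0] == pytest.approx(now.pct_poor.iloc[0])

    def test_empty_mask_reports_missing(self):
        pop = np.array([[10.0]])
        tbl = poverty_table(pop, np.array([[0.5]]),
                            PopulationGroups(
                                outside=np.array([[True]]),
                                flood_prone=np.array([[False]]),
                                benefit=np.array([[False]])))
        empty = tbl[tbl.group == "benefit"]
        assert empty.pct_poor.isna().all()


class TestWealthDistribution:
    def test_single_cell_single_bin_unit_area(self):
        w = np.array([[0.3]])
        pop = np.array([[7.0]])
        edges, dens = wealth_distribution(w, pop, np.array([[True]]),
                                          np.linspace(-1, 1, 11))
        widths = np.diff(edges)
        assert (dens > 0).sum() == 1
        assert (dens * widths).sum() == pytest.approx(1.0)

    def test_unit_area_for_random_masks(self, rng):
        w = rng.normal(0, 1, (10, 10))
        pop = rng.integers(0, 50, (10, 10)).astype(float)
        mask = rng.random((10, 10)) < 0.6
        edges, dens = wealth_distribution(w, pop, mask,
                                          np.linspace(-5, 5, 30))
        assert (dens * np.diff(edges)).sum() == pytest.approx(1.0)

    def test_pooled_histogram_is_population_weighted_mixture(self, rng):
        w = rng.normal(0, 1, (8, 8))
        pop = rng.integers(1, 20, (8, 8)).astype(float)
        top = np.zeros((8, 8), bool)
        top[:4] = True
        bins = np.linspace(-4, 4, 25)
        _, d_all = wealth_distribution(w, pop, np.ones((8, 8), bool), bins)
        _, d_top = wealth_distribution(w, pop, top, bins)
        _, d_bot = wealth_distribution(w, pop, ~top, bins)
        f = pop[top].sum() / pop.sum()
        assert np.allclose(d_all, f * d_top + (1 - f) * d_bot)

    def test_empty_mask_zero_density(self):
        edges, dens = wealth_distribution(np.zeros((2, 2)), np.zeros((2, 2)),
                                          np.zeros((2, 2), bool),
                                          np.linspace(-1, 1, 5))
        assert np.all(dens == 0)


def brute_force_exact_p(a, b):
    """Full enumeration over all C(n, n1) labelings of the pooled values."""
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    obs = abs((ranks[:n1].sum() - offset) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U1 == 0.0
        assert res.U2 == 9.0
        assert res.p == pytest.approx(0.1)
        assert res.exact

    def test_identical_samples(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.U1 == res.U2 == 2.0
        assert res.p == 1.0

    def test_u_sum_and_swap_symmetry(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            r1 = mann_whitney(a, b)
            r2 = mann_whitney(b, a)
            assert r1.U1 + r1.U2 == pytest.approx(r1.n1 * r1.n2)
            assert r1.U1 == pytest.approx(r2.U2)
            assert r1.p == pytest.approx(r2.p)

    def test_exact_mode_matches_enumeration_with_ties(self, rng):
        for _ in range(15):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            a = rng.integers(0, 4, size=n1).astype(float)  # heavy ties
            b = rng.integers(0, 4, size=n2).astype(float)
            res = mann_whitney(a, b)
            assert res.exact
            assert res.p == pytest.approx(brute_force_exact_p(a, b))

    def test_exact_mode_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            res = mann_whitney(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.U1 == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(0.0, 1.0, size=60)
        b = rng.normal(0.4, 1.0, size=80)
        res = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert not res.exact
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])


class TestWeightedSample:
    def test_counts_follow_population(self, rng):
        w = np.array([[1.0, 2.0]])
        pop = np.array([[3.0, 2.0]])
        vals = weighted_sample(w, pop, np.ones((1, 2), bool), rng)
        assert sorted(vals.tolist()) == [1.0, 1.0, 1.0, 2.0, 2.0]

    def test_budget_cap(self, rng):
        w = np.zeros((1, 1))
        pop = np.array([[1e6]])
        vals = weighted_sample(w, pop, np.ones((1, 1), bool), rng, budget=100)
        assert vals.size == 100
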