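"""Cashflow construction, discounting identities, sensitivity grid and the
5-ha regional exclusion rule."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

from hybridcoast.economics import (CashflowSeries, CostModel, RegionEconomics,
                                   YEARS, aggregate_regions, benefit_stream,
                                   cost_stream, discounted_bcr_npv,
                                   growth_factor, region_bca,
                                   sensitivity_grid)
from hybridcoast.errors import AssignmentError


class TestGrowthFactor:
    def test_zero_at_planting(self):
        assert growth_factor(2020, 2020) == 0.0

    def test_before_planting_zero(self):
        assert growth_factor(2015, 2020) == 0.0

    def test_saturation_99pct_at_ten_years(self):
        assert growth_factor(2030, 2020) == pytest.approx(0.99, abs=1e-12)

    def test_asymptote(self):
        assert growth_factor(2500, 2020) == pytest.approx(1.0, abs=1e-9)

    def test_monotone(self):
        years = np.arange(2020, 2101)
        g = growth_factor(years)
        assert np.all(np.diff(g) >= 0)
        assert np.all((0 <= g) & (g < 1))


class TestCostStream:
    def test_zero_area_zero_costs(self):
        assert np.all(cost_stream(0.0, CostModel()) == 0.0)

    def test_year0_with_opportunity_costs(self):
        # median implementation cost 8,143/ha: year-0 outlay 2.4x = 19,543.2
        c = cost_stream(1.0, CostModel(implementation_cost_per_ha=8143.0))
        assert c[0] == pytest.approx(8143.0 * 2.4)

    def test_year0_without_opportunity_costs(self):
        c = cost_stream(1.0, CostModel(implementation_cost_per_ha=8143.0),
                        include_opportunity=False)
        assert c[0] == pytest.approx(8143.0)

    def test_flat_gdp_maintenance_scaled_by_survival(self):
        cm = CostModel(implementation_cost_per_ha=1000.0, survival_rate=0.75)
        c = cost_stream(2.0, cm)
        assert np.allclose(c[1:], 0.75 * 0.01 * 1000.0 * 2.0)

    def test_maintenance_tracks_gdp_growth(self):
        cm = CostModel(implementation_cost_per_ha=1000.0, survival_rate=0.75)
        c = cost_stream(1.0, cm, gdp_growth_factor=lambda y: 1.02 ** (y - 2020))
        assert c[2] / c[1] == pytest.approx(1.02)


class TestBenefitStream:
    def test_zero_survival_zero_benefits(self):
        with pytest.raises(Exception):
            CostModel(survival_rate=0.0)  # rate must be in (0, 1)

    def test_planting_year_no_benefit(self):
        b = benefit_stream(lambda y: 100.0, CostModel())
        assert b[0] == 0.0

    def test_constant_potential_hand_value(self):
        # 0.75 survival x 0.99 regrowth x 100 at ten years
        b = benefit_stream(lambda y: 100.0, CostModel(survival_rate=0.75))
        assert b[10] == pytest.approx(74.25, abs=1e-9)


class TestDiscounting:
    def test_equal_streams_unit_bcr(self):
        s = CashflowSeries(YEARS.copy(), np.full(YEARS.size, 5.0),
                           np.full(YEARS.size, 5.0))
        res = discounted_bcr_npv(s, 0.07)
        assert res.bcr == pytest.approx(1.0)
        assert res.npv == pytest.approx(0.0, abs=1e-9)

    def test_one_period_break_even(self):
        b = np.zeros(YEARS.size)
        c = np.zeros(YEARS.size)
        c[0] = 100.0
        b[1] = 110.0
        res = discounted_bcr_npv(CashflowSeries(YEARS.copy(), b, c), 0.10)
        assert res.npv == pytest.approx(0.0, abs=1e-9)
        assert res.bcr == pytest.approx(1.0)

    def test_zero_costs_flagged(self):
        b = np.ones(YEARS.size)
        res = discounted_bcr_npv(
            CashflowSeries(YEARS.copy(), b, np.zeros(YEARS.size)), 0.05)
        assert not res.bcr_defined
        assert res.npv > 0

    def test_against_decimal_oracle(self, rng):
        getcontext().prec = 50
        for _ in range(10):
            b = rng.uniform(0, 100, size=YEARS.size)
            c = rng.uniform(0, 100, size=YEARS.size)
            r = float(rng.uniform(0.01, 0.12))
            res = discounted_bcr_npv(CashflowSeries(YEARS.copy(), b, c), r)
            dr = Decimal(repr(r))
            db = sum(Decimal(repr(float(x))) / (1 + dr) ** t
                     for t, x in enumerate(b))
            dc = sum(Decimal(repr(float(x))) / (1 + dr) ** t
                     for t, x in enumerate(c))
            assert res.disc_benefits == pytest.approx(float(db), rel=1e-10)
            assert res.disc_costs == pytest.approx(float(dc), rel=1e-10)
            assert res.npv == pytest.approx(float(db - dc), rel=1e-8)

    def test_linearity_in_benefits(self, rng):
        b = rng.uniform(0, 100, size=YEARS.size)
        c = rng.uniform(0, 100, size=YEARS.size)
        res1 = discounted_bcr_npv(CashflowSeries(YEARS.copy(), b, c), 0.05)
        res2 = discounted_bcr_npv(CashflowSeries(YEARS.copy(), 2 * b, c), 0.05)
        assert res2.npv == pytest.approx(
            2 * res1.disc_benefits - res1.disc_costs, rel=1e-10)


@pytest.fixture
def toy_region():
    return RegionEconomics(region_id="R1", country_id="C1", area_ha=50.0,
                           potential_benefit=lambda y: 2e5,
                           implementation_cost_per_ha=8143.0,
                           gdp_growth_factor=lambda y: 1.02 ** (y - 2020))


class TestSensitivityGrid:
    def test_sign_identity_everywhere(self, toy_region):
        df = sensitivity_grid([toy_region])
        assert len(df) == 4 * 3 * 2
        assert np.all(np.sign(df.npv.round(12)) == np.sign((df.bcr - 1).round(12)))

    def test_bcr_monotone_in_discount_rate(self, toy_region):
        df = sensitivity_grid([toy_region])
        sub = df[(df.s == 0.75) & df.opportunity].sort_values("r")
        assert np.all(np.diff(sub.bcr.values) <= 1e-12)

    def test_bcr_monotone_in_survival(self, toy_region):
        df = sensitivity_grid([toy_region])
        sub = df[(df.r == 0.05) & df.opportunity].sort_values("s")
        assert np.all(np.diff(sub.bcr.values) >= -1e-12)

    def test_excluding_opportunity_raises_bcr(self, toy_region):
        df = sensitivity_grid([toy_region])
        for (r, s), grp in df.groupby(["r", "s"]):
            excl = grp[~grp.opportunity].bcr.iloc[0]
            incl = grp[grp.opportunity].bcr.iloc[0]
            assert excl > incl

    def test_grid_matches_one_at_a_time(self, toy_region):
        df = sensitivity_grid([toy_region])
        for row in df.itertuples():
            single = region_bca(toy_region, r=row.r, s=row.s,
                                include_opportunity=row.opportunity)
            assert row.bcr == pytest.approx(single.bcr, rel=1e-12)
            assert row.npv == pytest.approx(single.npv, rel=1e-12)


class TestRegionalAggregation:
    def _meta(self):
        gdp = lambda y: 1.0  # noqa: E731
        return {"A": ("X", 8143.0, gdp), "B": ("X", 8143.0, gdp)}

    def test_region_below_5ha_excluded(self):
        agg = aggregate_regions({1: 4.9}, {1: lambda y: 10.0}, {1: "A"},
                                self._meta())
        assert agg.retained == []
        assert agg.excluded == [("A", 4.9)]

    def test_region_at_5ha_retained(self):
        agg = aggregate_regions({1: 5.0}, {1: lambda y: 10.0}, {1: "A"},
                                self._meta())
        assert [r.region_id for r in agg.retained] == ["A"]
        assert agg.excluded == []

    def test_benefits_additive_over_transects(self):
        agg = aggregate_regions({1: 5.0, 2: 6.0},
                                {1: lambda y: 10.0, 2: lambda y: 20.0},
                                {1: "A", 2: "A"}, self._meta())
        reg = agg.retained[0]
        assert reg.area_ha == pytest.approx(11.0)
        assert reg.potential_benefit(2050) == pytest.approx(30.0)

    def test_partition_invariance_of_totals(self):
        meta = self._meta()
        one = aggregate_regions({1: 5.0, 2: 6.0},
                                {1: lambda y: 10.0, 2: lambda y: 20.0},
                                {1: "A", 2: "A"}, meta)
        two = aggregate_regions({1: 5.0, 2: 6.0},
                                {1: lambda y: 10.0, 2: lambda y: 20.0},
                                {1: "A", 2: "B"}, meta)
        tot_one = sum(region_bca(r).npv for r in one.retained)
        tot_two = sum(region_bca(r).npv for r in two.retained)
        assert tot_one == pytest.approx(tot_two, rel=1e-12)

    def test_orphan_transect_rejected(self):
        with pytest.raises(AssignmentError):
            aggregate_regions({1: 5.0}, {1: lambda y: 1.0}, {}, self._meta())
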