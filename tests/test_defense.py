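"""Overtopping formulas, freeboard inversion, protection standards, crest
design and effective protection under sea-level rise."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from hybridcoast.defense import (DikeSpec, FLOPROS_TABLE, G, ProtectionStandard,
                                 design_crest, effective_protection,
                                 flopros_standard, mean_period,
                                 overtopping_discharge, required_freeboard)
from hybridcoast.errors import ConfigurationError, ParameterError

from conftest import make_transect


def oracle_q(hm0, rc, tan_alpha, tm):
    """Independent re-evaluation of the two mean-value branches."""
    s0 = 2 * math.pi * hm0 / (G * tm ** 2)
    xi = tan_alpha / math.sqrt(s0)
    q_break = (math.sqrt(G * hm0 ** 3) * (0.023 / math.sqrt(tan_alpha)) * xi
               * math.exp(-((2.7 * rc / (xi * hm0)) ** 1.3)))
    q_max = math.sqrt(G * hm0 ** 3) * 0.09 * math.exp(-((1.5 * rc / hm0) ** 1.3))
    return min(q_break, q_max)


class TestOvertopping:
    def test_zero_freeboard_maximum_branch(self):
        # at rc = 0 both exponentials are 1; the max branch is 0.09 sqrt(g h^3)
        q = overtopping_discharge(2.0, 0.0)
        assert q <= 0.09 * math.sqrt(G * 8.0) + 1e-12
        assert q == pytest.approx(oracle_q(2.0, 0.0, 1 / 3, mean_period(2.0)))

    def test_strictly_decreasing_in_freeboard(self):
        assert overtopping_discharge(2.0, 1.0) > overtopping_discharge(2.0, 2.0)

    def test_no_waves_no_overtopping(self):
        assert overtopping_discharge(0.0, 1.0) == 0.0

    def test_against_independent_formula_evaluation(self):
        hm0 = 2.0
        tm = math.sqrt(2 * math.pi * hm0 / (G * 0.04))  # steepness 0.04
        q = overtopping_discharge(hm0, 1.5, 1 / 3, tm)
        assert q == pytest.approx(oracle_q(hm0, 1.5, 1 / 3, tm), rel=1e-12)

    def test_random_states_match_oracle(self, rng):
        for _ in range(200):
            hm0 = rng.uniform(0.2, 5)
            rc = rng.uniform(0, 6)
            tan_alpha = rng.uniform(0.2, 0.5)
            tm = rng.uniform(3, 12)
            assert overtopping_discharge(hm0, rc, tan_alpha, tm) == \
                pytest.approx(oracle_q(hm0, rc, tan_alpha, tm), rel=1e-12)


class TestRequiredFreeboard:
    def test_zero_when_allowance_met_at_zero_freeboard(self):
        q0 = overtopping_discharge(0.5, 0.0)
        assert required_freeboard(0.5, q_allow=q0 * 1.01) == 0.0

    def test_no_waves_zero_freeboard(self):
        assert required_freeboard(0.0) == 0.0

    def test_round_trip_inversion(self, rng):
        for _ in range(300):
            hm0 = rng.uniform(0.3, 5)
            tm = rng.uniform(3, 12)
            tan_alpha = rng.uniform(0.2, 0.5)
            q_allow = 10 ** rng.uniform(-5, -1)
            rc = required_freeboard(hm0, tm, tan_alpha, q_allow)
            q = overtopping_discharge(hm0, rc, tan_alpha, tm)
            assert q <= q_allow * (1 + 1e-6)
            if rc > 0:
                assert q == pytest.approx(q_allow, rel=1e-6)

    def test_against_bisection_oracle(self, rng):
        for _ in range(50):
            hm0 = rng.uniform(0.3, 4)
            tm = rng.uniform(4, 10)
            q_allow = 10 ** rng.uniform(-5, -2)
            rc = required_freeboard(hm0, tm, 1 / 3, q_allow)
            if rc == 0.0:
                assert overtopping_discharge(hm0, 0.0, 1 / 3, tm) <= q_allow
                continue
            oracle = brentq(
                lambda r: overtopping_discharge(hm0, r, 1 / 3, tm) - q_allow,
                0.0, 100.0, xtol=1e-10)
            assert rc == pytest.approx(oracle, abs=1e-6)

    def test_larger_waves_need_higher_crests(self):
        rc1 = required_freeboard(1.0)
        rc2 = required_freeboard(2.0)
        assert rc2 > rc1 > 0


class TestFlopros:
    @pytest.mark.parametrize("income, urb, expected", [
        ("low", 0.1, 2), ("low", 0.9, 10),
        ("lower-middle", 0.2, 5), ("lower-middle", 0.7, 25),
        ("upper-middle", 0.4, 10), ("upper-middle", 0.5, 100),
        ("high", 0.1, 50), ("high", 0.9, 1000),
    ])
    def test_table(self, income, urb, expected):
        assert flopros_standard(income, urb).return_period == expected

    def test_range_bounds(self):
        for income, (rural, urban) in FLOPROS_TABLE.items():
            for rp in (rural, urban):
                assert 2 <= rp <= 1000

    def test_unknown_income_group(self):
        with pytest.raises(ConfigurationError):
            flopros_standard("oligarchy", 0.5)

    def test_standard_outside_range_rejected(self):
        with pytest.raises(ParameterError):
            ProtectionStandard(1.0)


class TestCrestDesign:
    def test_zero_waves_surge_only_design(self):
        tr = make_transect([0, 1000], [-5, -1])
        tr.hazard.hs_offshore[:] = 0.0
        dike = design_crest(tr, ProtectionStandard(100.0))
        assert dike.crest_elevation == pytest.approx(tr.hazard.wl(100.0))

    def test_restored_design_not_higher_than_current(self):
        tr = make_transect([0, 3000], [-5, 0.3], current=100.0, restorable=300.0)
        cur = design_crest(tr, ProtectionStandard(100.0), "current")
        res = design_crest(tr, ProtectionStandard(100.0), "restored")
        assert res.crest_elevation <= cur.crest_elevation

    def test_crest_composes_water_level_and_freeboard_oracle(self):
        from hybridcoast.foreshore import integrate_wave_transect
        tr = make_transect([0, 3000], [-5, 0.3], current=200.0)
        T = 100.0
        dike = design_crest(tr, ProtectionStandard(T))
        swl = tr.hazard.wl(T)
        hs = integrate_wave_transect(tr, swl, tr.hazard.hs(T), 200.0)
        rc = brentq(lambda r: overtopping_discharge(hs, r) - 0.001, 0, 50,
                    xtol=1e-9) if overtopping_discharge(hs, 0) > 0.001 else 0.0
        assert dike.crest_elevation == pytest.approx(swl + rc, abs=1e-5)


class TestEffectiveProtection:
    def test_design_identity_at_baseline(self):
        tr = make_transect([0, 3000], [-5, 0.3], current=150.0)
        T_std = 100.0
        dike = design_crest(tr, ProtectionStandard(T_std))
        got = effective_protection(tr, dike, "current", year=2020)
        # within one grid step of the design standard (log grid, 60 points)
        step = (1000.0 / 2.0) ** (1.0 / 59.0)
        assert T_std / step <= got <= T_std * step

    def test_restoration_raises_protection(self):
        tr = make_transect([0, 3000], [-5, 0.3], current=100.0,
                           restorable=400.0)
        dike = design_crest(tr, ProtectionStandard(50.0))
        cur = effective_protection(tr, dike, "current")
        res = effective_protection(tr, dike, "restored")
        assert res >= cur

    def test_dense_scan_oracle(self):
        tr = make_transect([0, 3000], [-5, 0.3], current=150.0)
        dike = design_crest(tr, ProtectionStandard(100.0))
        grid = np.exp(np.linspace(np.log(2), np.log(1000), 60))
        dense = np.exp(np.linspace(np.log(2), np.log(1000), 500))

        def requirement(T):
            from hybridcoast.foreshore import integrate_wave_transect
            swl = tr.hazard.wl(T)
            hs = integrate_wave_transect(tr, swl, tr.hazard.hs(T), 150.0)
            return swl + required_freeboard(hs)

        ok = [T for T in dense if requirement(T) <= dike.crest_elevation + 1e-9]
        brute = max(ok) if ok else 2.0
        got = effective_protection(tr, dike, "current")
        # agreement within one grid step of the 60-point search
        step = (1000.0 / 2.0) ** (1.0 / 59.0)
        assert brute / step <= got <= brute * step

    def test_substandard_flag(self):
        tr = make_transect([0, 3000], [-5, 0.3], current=0.0)
        dike = DikeSpec(crest_elevation=0.1)  # hopeless crest
        level = effective_protection(tr, dike, "current", with_flag=True)
        assert level.return_period == 2.0
        assert level.substandard

    def test_slr_degrades_protection(self, small_world):
        tr = make_transect([0, 3000], [-5, 0.3], current=150.0)
        dike = design_crest(tr, ProtectionStandard(100.0))
        scen = small_world.scenarios[0]
        now = effective_protection(tr, dike, "current", 2020, scen)
        later = effective_protection(tr, dike, "current", 2080, scen)
        assert later <= now
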