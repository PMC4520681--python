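"""Selectivity scenarios, calibration recovery and yield aggregation."""

import numpy as np
import pytest

from oceanspectra.fisheries import (
    SCENARIOS,
    aggregate_yields,
    calibrate_resource,
    fishing_mortality_array,
    length_to_mass,
    mass_to_length,
    scenario_fishing_mortality,
    yield_curve,
)
from oceanspectra.trait import TraitParams, build_community, equilibrium_run


class TestLengthMass:
    @pytest.mark.parametrize(
        "mass,length",
        [(0.01, 1.0), (1e3, 46.4), (1e6, 464.2)],
    )
    def test_cube_law(self, mass, length):
        assert mass_to_length(mass) == pytest.approx(length, abs=0.05)

    def test_round_trip(self):
        m = np.logspace(-2, 6, 9)
        np.testing.assert_allclose(length_to_mass(mass_to_length(m)), m, rtol=1e-12)

    def test_table_lengths_match_model_species(self):
        m_inf = 10.0 ** np.linspace(0, 6, 13)
        quoted = [r.l_inf for r in SCENARIOS["A"].rows]
        for m, q in zip(m_inf, quoted):
            assert round(mass_to_length(m)) == q


class TestScenarioMortality:
    def test_knife_edge(self):
        t = SCENARIOS["A"]
        below = scenario_fishing_mortality(t, 22, length_to_mass(7.9), "LME")
        above = scenario_fishing_mortality(t, 22, length_to_mass(8.1), "LME")
        assert below == 0.0
        assert above == pytest.approx(0.43)

    def test_multiplier_and_temperature_scaling(self):
        f = scenario_fishing_mortality(SCENARIOS["A"], 32, 1e3, "LME", multiplier=2.0, tau_t=1.5)
        assert f == pytest.approx(0.49 * 2.0 * 1.5)

    def test_lme_only_rows_inactive_in_fao(self):
        t = SCENARIOS["B"]
        m = np.logspace(0, 2, 20)
        assert np.all(scenario_fishing_mortality(t, 22, m, "FAO") == 0.0)
        assert np.any(scenario_fishing_mortality(t, 22, m, "LME") > 0.0)

    def test_scenario_d_small_species_never_fished(self):
        for l_inf in (5, 7, 10, 15, 22, 32):
            assert np.all(
                scenario_fishing_mortality(SCENARIOS["D"], l_inf, np.logspace(-1, 4, 30), "LME")
                == 0.0
            )

    def test_scenario_d_reference_row(self):
        # L_inf 46, L_c 20: F = 0.3 above 0.01*20^3 = 80 g
        f = scenario_fishing_mortality(SCENARIOS["D"], 46, 80.0, "LME")
        assert f == pytest.approx(0.3)

    def test_scenario_c_shared_band_for_large_species(self):
        for l_inf in (147, 215, 316, 464):
            row = SCENARIOS["C"].row_for(l_inf)
            assert row.l_c == 48
            assert row.f == pytest.approx(0.13)

    def test_mortality_array_shape_and_tau(self, ref_cell):
        comm = build_community(ref_cell)
        arr = fishing_mortality_array(comm, SCENARIOS["A"], "LME", multiplier=1.0)
        assert arr.shape == comm.n_c.shape
        expected_max = 0.49 * comm.tau_t  # highest Table F times tau_T
        assert arr.max() == pytest.approx(expected_max)


class TestCalibration:
    def test_recovers_parameters_from_self_generated_baseline(self, ref_cell):
        """Calibrating to a baseline the trait model itself produced must
        recover kappa within 1% (and reproduce the slope)."""
        true = TraitParams(kappa=0.04, r0=1.1, gamma=None)
        eq = equilibrium_run(build_community(ref_cell, true), max_years=480)
        logw = np.log10(eq.community.w)
        sel = (logw >= 2) & (logw <= 4)
        b_base = float(eq.mean_biomass_per_bin()[sel].sum())
        cal = calibrate_resource(ref_cell, eq.b_c, b_base)
        assert cal.kappa == pytest.approx(0.04, rel=0.01)
        assert cal.slope_rel_diff < 0.02

    def test_median_calibration_close(self, median_cal):
        assert median_cal.converged
        assert median_cal.slope_rel_diff <= 0.02
        assert abs(median_cal.log_biomass_diff) < 0.05


class TestYieldCurves:
    def test_zero_multiplier_zero_yield(self, curves_ad):
        for yc in curves_ad.values():
            assert yc.yields["all"][0] == 0.0

    def test_dome_shape_with_interior_maximum(self, curves_ad):
        for yc in curves_ad.values():
            i = int(np.argmax(yc.yields["all"]))
            assert 0 < i < len(yc.multipliers) - 1
            assert yc.yields["all"][-1] < yc.mmsy

    def test_unselective_scenario_outyields_selective(self, curves_ad):
        """Scenario A fishes a superset of sizes, so its yield dominates
        scenario D at every multiplier."""
        assert np.all(curves_ad["A"].yields["all"] >= curves_ad["D"].yields["all"] - 1e-12)

    def test_prey_release_of_small_consumers(self, curves_ad):
        """With small species unfished (D), the 100 g - 1 kg class rises
        above its unfished biomass at moderate F."""
        assert curves_ad["D"].biomass_ratio["100g_1kg"].max() > 1.0

    def test_total_biomass_nonincreasing_under_broad_selection(self, curves_ad):
        ratios = curves_ad["A"].biomass_ratio["total_gt_100g"]
        assert np.all(np.diff(ratios) <= 1e-6)

    def test_mmsy_bounds_tabulated_yields(self, curves_ad):
        yc = curves_ad["A"]
        assert all(yc.mmsy >= y for y in yc.yields["all"])


class TestAggregation:
    def test_single_region_identity(self, curves_ad):
        yc = curves_ad["A"]
        agg = aggregate_yields([yc])
        np.testing.assert_allclose(agg.yield_tonnes("all"), yc.yield_tonnes("all"))

    def test_two_identical_regions_double(self, curves_ad):
        yc = curves_ad["A"]
        agg = aggregate_yields([yc, yc])
        np.testing.assert_allclose(agg.yield_tonnes("all"), 2 * yc.yield_tonnes("all"))

    def test_global_mmsy_at_most_sum_of_regional(self, curves_ad):
        a, d = curves_ad["A"], curves_ad["D"]
        agg = aggregate_yields([a, d])
        assert np.max(agg.yield_tonnes("all")) <= np.max(a.yield_tonnes("all")) + np.max(
            d.yield_tonnes("all")
        ) + 1e-9

    def test_mismatched_grids_rejected(self, curves_ad):
        yc = curves_ad["A"]
        from dataclasses import replace

        other = replace(yc, multipliers=yc.multipliers[:-1])
        with pytest.raises(ValueError):
            aggregate_yields([yc, other])
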