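"""Dynamic trait-based model: grids, rates, equilibria, tuning.

Analytic limits (semichemostat fixed point, zero-prey feeding level,
power-law kernel averages) serve as oracles; the heavier equilibrium
checks reuse the session fixtures.
"""

import numpy as np
import pytest
from dataclasses import replace

from oceanspectra.fisheries import mass_to_length
from oceanspectra.trait import (
    GRID_SIZE,
    N_SPECIES,
    TraitParams,
    build_community,
    community_slope,
    equilibrium_run,
    project,
    realised_ppmr,
    temp_multiplier,
)


class TestTempMultiplier:
    @pytest.mark.parametrize(
        "t_k,expected",
        [(283.0, 1.0), (293.0, 2.315), (273.0, 0.406)],
    )
    def test_reference_values(self, t_k, expected):
        assert temp_multiplier(t_k) == pytest.approx(expected, rel=2e-3)

    def test_intake_metabolism_ratio_invariant(self):
        """Scaling intake and metabolism by the same tau_T leaves their
        ratio unchanged at every size."""
        p = TraitParams()
        w = np.logspace(-2, 5, 20)
        for tau in (0.5, 1.0, 2.32):
            ratio = (p.h * w**p.n * tau) / (p.k_s * w**p.p * tau)
            np.testing.assert_allclose(ratio, p.h / p.k_s * w ** (p.n - p.p))


class TestBuildCommunity:
    def test_thirteen_species_on_joint_grid(self, ref_cell):
        comm = build_community(ref_cell)
        assert comm.n_c.shape == (N_SPECIES, GRID_SIZE)
        assert comm.m_inf[0] == pytest.approx(1.0)
        assert comm.m_inf[-1] == pytest.approx(1e6)
        # largest species corresponds to the quoted 464 cm asymptotic length
        assert round(mass_to_length(comm.m_inf[-1])) == 464
        assert comm.w[0] == pytest.approx(1e-10)
        assert comm.w[-1] == pytest.approx(1e6)

    def test_grid_log_uniform(self, ref_cell):
        comm = build_community(ref_cell)
        steps = np.diff(np.log(comm.w))
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_resource_starts_at_capacity(self, ref_cell):
        comm = build_community(ref_cell)
        p = comm.params
        sel = comm.w <= 0.1
        np.testing.assert_allclose(comm.n_r[sel], p.kappa * comm.w[sel] ** (-p.lam))
        assert np.all(comm.n_r[~sel] == 0.0)


class TestProjection:
    def test_resource_fixed_point_without_consumers(self, ref_cell):
        """A grazed-free semichemostat sits exactly at carrying capacity."""
        comm = build_community(ref_cell)
        comm.n_c[:] = 0.0
        cap = comm.n_r.copy()
        project(comm, 100.0)
        np.testing.assert_allclose(comm.n_r, cap, rtol=1e-9)
        assert np.all(comm.n_c == 0.0)

    def test_zero_prey_means_zero_feeding(self, ref_cell):
        from oceanspectra.trait import _rates

        comm = build_community(ref_cell)
        comm.n_c[:] = 0.0
        comm.n_r[:] = 0.0
        rates = _rates(comm)
        assert np.all(rates["f"] == 0.0)
        assert np.all(rates["recruitment"] == 0.0)

    def test_feeding_level_strictly_inside_unit_interval(self, ref_cell):
        from oceanspectra.trait import _rates

        comm = build_community(ref_cell)
        project(comm, 20.0)
        f = _rates(comm)["f"]
        has_prey = _rates(comm)["encounter"] > 0
        assert np.all(f[has_prey] > 0.0)
        assert np.all(f < 1.0)

    def test_resource_never_exceeds_capacity(self, ref_cell):
        comm = build_community(ref_cell)
        p = comm.params
        project(comm, 50.0)
        cap = p.kappa * comm.w ** (-p.lam)
        sel = comm.w <= 0.1
        assert np.all(comm.n_r[sel] <= cap[sel] * (1 + 1e-9))

    def test_abundances_stay_finite_and_nonnegative(self, ref_cell):
        comm = build_community(ref_cell)
        project(comm, 30.0)
        assert np.all(np.isfinite(comm.n_c))
        assert np.all(comm.n_c >= 0.0)


class TestEquilibrium:
    def test_kappa_is_a_pure_scale(self, ref_cell):
        """Doubling kappa doubles every density and leaves the slope
        untouched (the search coefficient is derived from kappa)."""
        eq1 = equilibrium_run(build_community(ref_cell, TraitParams()), max_years=300)
        eq2 = equilibrium_run(build_community(ref_cell, TraitParams(kappa=0.2)), max_years=300)
        np.testing.assert_allclose(2 * eq1.mean_n_c, eq2.mean_n_c, rtol=1e-8)
        assert eq2.b_c == pytest.approx(eq1.b_c, abs=1e-9)

    def test_all_species_persist_unfished(self, ref_cell):
        eq = equilibrium_run(build_community(ref_cell), max_years=480)
        biomass = eq.mean_species_biomass()
        assert np.all(biomass > 1e-4)  # g m-2; every species holds stock

    def test_converged_run_is_stationary(self, ref_cell):
        from oceanspectra.trait import _window_average

        comm = build_community(ref_cell)
        eq = equilibrium_run(comm, max_years=480)
        assert eq.converged
        mean_c, _, _ = _window_average(eq.community, 60.0, 0.1)
        b = community_slope(mean_c.sum(axis=0) * comm.w * comm.dw, comm.w)
        assert b == pytest.approx(eq.b_c, abs=0.01 * abs(eq.b_c) + 1e-4)

    def test_zero_fishing_zero_yield(self, ref_cell):
        eq = equilibrium_run(build_community(ref_cell), max_years=300)
        assert np.all(eq.yield_per_area == 0.0)

    def test_realised_ppmr_near_preference_target(self, ref_cell):
        """The default preference is tuned so the realised (diet-weighted)
        log10 PPMR at the reference cell is 3 within 0.05."""
        eq = equilibrium_run(build_community(ref_cell), max_years=480)
        assert realised_ppmr(eq.community) == pytest.approx(3.0, abs=0.05)


class TestRealisedPPMR:
    def test_power_law_prey_closed_form(self, ref_cell):
        """For power-law prey w^-lam the diet-weighted mean log10 ratio
        is log10(beta) - (2 - lam) sigma^2 / ln 10: with lam > 2 small
        prey are relatively more abundant, so the realised ratio sits
        above the preference (lognormal kernel tilt, computed
        analytically from the Gaussian integral)."""
        comm = build_community(ref_cell)
        p = comm.params
        # artificial state: prey power law continuous across the whole
        # grid, predators confined to a band whose kernels are fully
        # covered by the prey field
        comm.n_r = p.kappa * comm.w ** (-p.lam)
        comm.n_c[:] = 0.0
        band = (comm.w >= 1e2) & (comm.w <= 1e4)
        # predator density tiny so it does not perturb the prey field
        comm.n_c[5, band] = 1e-8 * p.kappa * comm.w[band] ** (-p.lam)
        expected = np.log10(p.beta_pref) - (2.0 - p.lam) * p.sigma_pref**2 / np.log(10.0)
        assert realised_ppmr(comm) == pytest.approx(expected, abs=0.02)


class TestCommunitySlope:
    def test_recovers_exact_power_law(self, ref_cell):
        comm = build_community(ref_cell)
        b = 10.0 ** (-0.25 * np.log10(comm.w) + 1.0)
        assert community_slope(b, comm.w) == pytest.approx(-0.25, abs=1e-9)

    def test_too_few_bins_rejected(self, ref_cell):
        comm = build_community(ref_cell)
        b = np.zeros_like(comm.w)
        with pytest.raises(ValueError):
            community_slope(b, comm.w)
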