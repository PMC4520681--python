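"""Phytoplankton size structure, tail extension and export ratio.

The quadrature oracles integrate the production densities directly
(scipy.integrate.quad) and are independent of the closed forms they
check.
"""

import numpy as np
import pytest
from scipy.integrate import quad

from oceanspectra import constants as K
from oceanspectra.phyto import (
    DegenerateDrawError,
    PhytoSpectrum,
    export_ratio,
    export_state,
    extend_tails,
    phyto_regressions,
    relative_export_multiplier,
    small_fraction,
)


class TestRegressions:
    def test_unit_production_leaves_intercepts(self):
        spec = phyto_regressions(1.0, 20.0)
        assert spec.b_p == pytest.approx(-1.715)
        assert spec.a_p == pytest.approx(8.087)

    def test_median_mass_at_20C(self):
        # 10^(-0.545 - 0.078*20) evaluated directly
        spec = phyto_regressions(1.0, 20.0)
        assert spec.m_p50 == pytest.approx(7.852e-3, rel=1e-3)

    def test_range_factor_at_0C(self):
        assert phyto_regressions(1.0, 0.0).m_p1090 == pytest.approx(1.845, rel=1e-3)

    def test_rejects_nonpositive_production(self):
        with pytest.raises(ValueError):
            phyto_regressions(0.0, 10.0)


class TestExtendTails:
    def test_zero_width_distribution_collapses(self):
        spec = PhytoSpectrum(b_p=-1.7, a_p=8.0, m_p50=0.5, m_p1090=1.0)
        out = extend_tails(spec)
        assert out.m_p0 == pytest.approx(0.5)
        assert out.m_p100 == pytest.approx(0.5)

    def test_flags_slope_at_integrable_limit(self):
        with pytest.raises(DegenerateDrawError):
            extend_tails(PhytoSpectrum(b_p=-1.0, a_p=8.0, m_p50=0.5, m_p1090=2.0))

    def test_bounds_ordering(self):
        out = extend_tails(phyto_regressions(0.5, 15.0))
        assert out.m_p0 < out.m_p10 < out.m_p50 < out.m_p90 < out.m_p100

    def test_tails_add_one_quarter_of_central_production(self):
        """Integrated m^b production over [m0, m100] is 1.25x [m10, m90]."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            spec = PhytoSpectrum(
                b_p=float(rng.uniform(-1.9, -1.3)),
                a_p=8.0,
                m_p50=float(10.0 ** rng.uniform(-2, 0)),
                m_p1090=float(10.0 ** rng.uniform(0.05, 0.9)),
            )
            try:
                out = extend_tails(spec)
            except DegenerateDrawError:
                continue
            b = out.b_p

            def density(m):
                return m**b

            full, _ = quad(density, out.m_p0, out.m_p100)
            central, _ = quad(density, out.m_p10, out.m_p90)
            assert full == pytest.approx(1.25 * central, rel=1e-7)


def _spectrum_with_bounds(b_p, a_p, x0, x100):
    """Spectrum with tail bounds set directly (for small-fraction tests)."""
    return PhytoSpectrum(
        b_p=b_p,
        a_p=a_p,
        m_p50=10.0 ** ((x0 + x100) / 2),
        m_p1090=1.0,
        m_p0=10.0**x0,
        m_p100=10.0**x100,
    )


class TestSmallFraction:
    def test_worked_closed_form(self):
        # hand-evaluated quadratic antiderivative for the quoted inputs
        spec = _spectrum_with_bounds(-1.715, 8.087, -2.0, 2.0)
        phi = small_fraction(spec, m_ref=10.0**0.5)
        assert phi == pytest.approx(0.7244, abs=2e-4)

    def test_clamps_outside_bounds(self):
        spec = _spectrum_with_bounds(-1.7, 8.0, 0.0, 2.0)
        assert small_fraction(spec, m_ref=0.5) == 0.0
        assert small_fraction(spec, m_ref=200.0) == 1.0

    def test_agrees_with_quadrature_on_random_spectra(self):
        """Closed form vs numeric integral of the production density,
        1000 random valid spectra, relative error below 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            b_p = float(rng.uniform(-2.2, -1.2))
            a_p = float(rng.uniform(6.0, 9.0))
            x0 = float(rng.uniform(-3.0, 0.5))
            x100 = float(rng.uniform(x0 + 0.2, 3.5))
            x_ref = float(rng.uniform(x0 + 1e-3, x100 - 1e-3))
            spec = _spectrum_with_bounds(b_p, a_p, x0, x100)
            phi = small_fraction(spec, m_ref=10.0**x_ref)

            def density(x):
                return b_p * x + a_p

            num, _ = quad(density, x0, x_ref)
            den, _ = quad(density, x0, x100)
            expected = min(1.0, max(0.0, num / den))
            assert phi == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_full_chain_fraction_is_unity_for_ocean_forcing(self):
        # with the regressions' mass scales the 5 um reference exceeds the
        # whole distribution, so all production counts as small cells
        spec = extend_tails(phyto_regressions(0.5, 15.0))
        assert small_fraction(spec) == 1.0

    def test_monotone_in_median_mass(self):
        """phi_s rises as the distribution shifts to smaller cells."""
        phis = []
        for shift in (0.0, 0.5, 1.0):
            spec = _spectrum_with_bounds(-1.7, 8.0, 0.0 - shift, 2.5 - shift)
            phis.append(small_fraction(spec, m_ref=12.9))
        assert phis[0] < phis[1] < phis[2]


class TestExportRatio:
    def test_remineralisation_coefficient_at_200m(self):
        # R = Z D / S enters as phi_e = (...)/(1+R); at 200 m R = 0.8,
        # and with only small cells at 0 degC the ratio is 0.14/1.8
        assert export_ratio(1.0, 0.0, 200.0) == pytest.approx(0.14 / 1.8, rel=1e-9)

    def test_decreases_with_temperature(self):
        z, phi_s = 150.0, 0.6
        vals = [export_ratio(phi_s, t, z) for t in (0.0, 10.0, 20.0, 30.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_bounded_on_forcing_envelope(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            phi = export_ratio(
                float(rng.uniform(0, 1)),
                float(rng.uniform(-2, 30)),
                float(rng.uniform(10, 6000)),
            )
            assert 0.0 <= phi <= 1.0

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            export_ratio(1.5, 10.0, 100.0)
        with pytest.raises(ValueError):
            export_ratio(0.5, 10.0, 0.0)


class TestRelativeExportMultiplier:
    @pytest.mark.parametrize(
        "phi_e_z,phi_e_ref,expected",
        [(0.1, 0.1, 1.0), (0.1, 0.2, 1.1), (0.3, 0.1, 0.8)],
    )
    def test_identity_and_arithmetic(self, phi_e_z, phi_e_ref, expected):
        assert relative_export_multiplier(phi_e_z, phi_e_ref) == pytest.approx(expected)

    def test_chain_consistency(self):
        spec = extend_tails(phyto_regressions(0.5, 15.0))
        st = export_state(spec, 15.0, 180.0)
        assert st.phi_s + st.phi_l == pytest.approx(1.0, abs=1e-12)
        assert st.tau_r == pytest.approx(1.0 + st.phi_e_ref - st.phi_e_z, rel=1e-12)
        # shallower analysis depth exports more, so tau_r < 1 above 200 m
        assert st.phi_e_z > st.phi_e_ref
        assert st.tau_r < 1.0
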