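"""Phytoplankton size structure and particle export.

The phytoplankton community that supports consumer production is described
by four empirical metrics regressed on primary production P_P and
temperature T_C:

* ``b_p``   slope of the phytoplankton biomass size spectrum
            (log10 B, pg C m-3, vs log10 M, pg C);
* ``a_p``   intercept of that spectrum;
* ``m_p50`` cell mass (pg C) at 50% of cumulative primary production;
* ``m_p1090`` mass-range factor m_p90/m_p10 covering the central 80% of
  production (its log10 is the range in log-mass units; reading the
  regressed quantity as the log-range itself would make the upper-tail
  extension below unsolvable over most of the warm ocean, since the
  spectrum slope is well below -1).

From these, closed-form tail extensions give the distribution bounds
``m_p0``/``m_p100`` (each tail incorporating a further 10% of production so
the integral covers all of P_P), the fraction of production by small cells
(<= 12.9 pg C, i.e. 5 um equivalent spherical diameter), the particle
export ratio at any depth, and finally the relative-export multiplier
``tau_r`` applied to the trophic transfer efficiency of the first food-web
step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import constants as K
from .constants import PHYTO_REGRESSIONS, RegressionRow

__all__ = [
    "PhytoSpectrum",
    "ExportState",
    "DegenerateDrawError",
    "phyto_regressions",
    "extend_tails",
    "small_fraction",
    "export_ratio",
    "relative_export_multiplier",
    "export_state",
]


class DegenerateDrawError(ValueError):
    """A Monte-Carlo parameter draw produced an unusable phytoplankton
    spectrum (slope at the integrable limit, non-positive radicand in a
    tail extension, or a zero-measure production integral)."""


@dataclass
class PhytoSpectrum:
    """Phytoplankton production-spectrum summary for one cell and draw.

    Masses in pg C; ``m_p1090`` is the central-80%-of-production mass
    range factor (m_p90 / m_p10). Tail bounds are None until
    :func:`extend_tails` has been applied.
    """

    b_p: float
    a_p: float
    m_p50: float
    m_p1090: float
    m_p0: float | None = None
    m_p100: float | None = None

    @property
    def log_range(self) -> float:
        """log10 of the 10-90% production mass range, log10(m_p90/m_p10)."""
        return float(np.log10(self.m_p1090))

    @property
    def m_p10(self) -> float:
        # the 10-90% production range is placed symmetrically about
        # log10 m_p50 (the metrics themselves do not fix the placement)
        return 10.0 ** (np.log10(self.m_p50) - self.log_range / 2.0)

    @property
    def m_p90(self) -> float:
        return 10.0 ** (np.log10(self.m_p50) + self.log_range / 2.0)


@dataclass(frozen=True)
class ExportState:
    """Export-ratio quantities for one cell and draw."""

    phi_s: float  # fraction of production by small cells
    phi_e_z: float  # export ratio at the analysis depth
    phi_e_ref: float  # export ratio at the 200 m reference depth
    tau_r: float  # relative export multiplier

    @property
    def phi_l(self) -> float:
        return 1.0 - self.phi_s


def phyto_regressions(
    pp: float,
    t_c: float,
    coeffs: dict[str, RegressionRow] | None = None,
) -> PhytoSpectrum:
    """Evaluate the four size-structure regressions at (P_P, T_C).

    ``coeffs`` maps metric name to a :class:`RegressionRow`; defaults are
    the fitted means. Slope and intercept depend on log10 P_P only;
    ``m_p50`` and ``m_p1090`` are 10**(linear predictor) with temperature
    terms.
    """
    if pp <= 0:
        raise ValueError("primary production must be positive")
    c = coeffs or PHYTO_REGRESSIONS
    lp = np.log10(pp)

    def lin(row: RegressionRow) -> float:
        return row.alpha + row.beta1 * lp + row.beta2 * t_c

    return PhytoSpectrum(
        b_p=lin(c["b_p"]),
        a_p=lin(c["a_p"]),
        m_p50=10.0 ** lin(c["m_p50"]),
        m_p1090=10.0 ** lin(c["m_p1090"]),
    )


def extend_tails(spec: PhytoSpectrum) -> PhytoSpectrum:
    """Add the distribution bounds ``m_p0`` and ``m_p100``.

    Each tail extends the power-law production density m**b_p to capture an
    additional 10% of integrated production beyond the 10% and 90%
    quantiles, so that integrated production over [m_p0, m_p100] equals
    1.25x that over [m_p10, m_p90]:

        m_p0^(b+1)   = (5/4) m_p10^(b+1) - (1/4) m_p50^(b+1)
        m_p100^(b+1) = (5/4) m_p90^(b+1) - (1/4) m_p50^(b+1)

    Raises :class:`DegenerateDrawError` when b_p is at the integrable
    limit (-1) or a radicand is non-positive.
    """
    b1 = spec.b_p + 1.0
    if abs(b1) < 1e-9:
        raise DegenerateDrawError("phytoplankton slope at the b_p = -1 limit")
    m50, m10, m90 = spec.m_p50, spec.m_p10, spec.m_p90
    rad0 = -1.25 * m50**b1 + 1.25 * m10**b1 + m50**b1
    rad100 = 1.25 * m90**b1 - 1.25 * m50**b1 + m50**b1
    if rad0 <= 0 or rad100 <= 0:
        raise DegenerateDrawError("non-positive radicand in tail extension")
    m_p0 = rad0 ** (1.0 / b1)
    m_p100 = rad100 ** (1.0 / b1)
    if not (np.isfinite(m_p0) and np.isfinite(m_p100)) or m_p0 > m_p100:
        raise DegenerateDrawError("tail extension produced invalid bounds")
    return replace(spec, m_p0=float(m_p0), m_p100=float(m_p100))


def small_fraction(spec: PhytoSpectrum, m_ref: float = K.M_REF_SMALL_PG) -> float:
    """Fraction of phytoplankton production by cells of mass <= ``m_ref``.

    The production density in x = log10 M is taken as the spectrum line
    b_p*x + a_p; phi_s is its integral from x0 = log10 m_p0 up to
    x_ref = log10 m_ref as a fraction of the integral over the full range,
    using the antiderivative b_p*x^2/2 + a_p*x. Clamped to [0, 1]; if
    m_ref lies outside [m_p0, m_p100] the fraction is exactly 0 or 1.
    """
    if spec.m_p0 is None or spec.m_p100 is None:
        raise ValueError("call extend_tails before small_fraction")
    if m_ref <= spec.m_p0:
        return 0.0
    if m_ref >= spec.m_p100:
        return 1.0
    x0 = np.log10(spec.m_p0)
    x100 = np.log10(spec.m_p100)
    xr = np.log10(m_ref)

    def F(x: float) -> float:
        return 0.5 * spec.b_p * x * x + spec.a_p * x

    denom = F(x100) - F(x0)
    if denom == 0.0:
        raise DegenerateDrawError("zero production integral in small_fraction")
    return float(min(1.0, max(0.0, (F(xr) - F(x0)) / denom)))


def export_ratio(
    phi_s: float,
    t_c: float,
    z: float,
    *,
    k_d: float = K.K_D,
    phi_sd: float = K.PHI_SD,
    phi_ld: float = K.PHI_LD,
    r_b: float = K.R_B,
    d_remin: float = K.D_REMIN,
    s_sink: float = K.S_SINK,
) -> float:
    """Particle export ratio (pe-ratio) at depth ``z`` (m).

    Dunne-type formulation: the fraction of primary production exported as
    sinking particles past depth z given the small-cell production share
    phi_s and temperature t_c (degC),

        R     = z * D / S
        phi_e = (exp(T_C k_D) (phi_SD phi_S + phi_LD phi_L)
                 + R r_B phi_L) / (1 + R)

    with phi_l = 1 - phi_s. The temperature term (k_D < 0) lowers export
    in warm water; R is the vertically integrated remineralisation
    coefficient.
    """
    if not 0.0 <= phi_s <= 1.0:
        raise ValueError("phi_s must lie in [0, 1]")
    if z <= 0:
        raise ValueError("depth must be positive")
    phi_l = 1.0 - phi_s
    r = z * d_remin / s_sink
    phi_e = (np.exp(t_c * k_d) * (phi_sd * phi_s + phi_ld * phi_l) + r * r_b * phi_l) / (
        1.0 + r
    )
    return float(phi_e)


def relative_export_multiplier(phi_e_z: float, phi_e_ref: float) -> float:
    """Relative export multiplier tau_r = 1 + phi_e_ref - phi_e_z.

    Scales the first-step transfer efficiency for export losses at the
    analysis depth relative to the 200 m reference: shallower analysis
    depths (higher export, phi_e_z > phi_e_ref) reduce the energy retained
    by the pelagic food web (tau_r < 1), deeper ones increase it.
    """
    return 1.0 + phi_e_ref - phi_e_z


def export_state(
    spec: PhytoSpectrum,
    t_c: float,
    z_analysis: float,
    *,
    m_ref: float = K.M_REF_SMALL_PG,
    ref_depth: float = K.REF_EXPORT_DEPTH_M,
) -> ExportState:
    """Convenience chain: small fraction -> export ratios -> tau_r."""
    phi_s = small_fraction(spec, m_ref)
    phi_e_z = export_ratio(phi_s, t_c, z_analysis)
    phi_e_ref = export_ratio(phi_s, t_c, ref_depth)
    return ExportState(
        phi_s=phi_s,
        phi_e_z=phi_e_z,
        phi_e_ref=phi_e_ref,
        tau_r=relative_export_multiplier(phi_e_z, phi_e_ref),
    )
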