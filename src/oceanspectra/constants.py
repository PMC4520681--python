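"""Default parameter values for the macroecological size-spectrum model.

Two groups of constants are collected here:

* regression coefficients linking phytoplankton community size structure
  (spectrum slope/intercept, median-production cell mass and the 10-90%
  production mass range) to primary production and temperature, each with
  the standard deviation used for Monte-Carlo parameter sampling;
* fixed physical/ecological constants: the export-ratio (pe-ratio)
  parameters of the Dunne-type particle-export model, the metabolic
  production scaling, carbon/wet-mass conversions and reference depths.

All values are module-level defaults; every model entry point accepts
overrides so none of these are hard-wired into the computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# --- phytoplankton size-structure regressions ------------------------------
# Each row: intercept alpha, coefficient on log10(primary production) beta1,
# coefficient on temperature (deg C) beta2, with sampling s.d. (0 = fixed).
# Masses in pg C; primary production in g C m-2 d-1.


@dataclass(frozen=True)
class RegressionRow:
    alpha: float
    beta1: float
    beta2: float
    sd_alpha: float = 0.0
    sd_beta1: float = 0.0
    sd_beta2: float = 0.0


PHYTO_REGRESSIONS: dict[str, RegressionRow] = {
    # slope of the phytoplankton biomass spectrum (log10 B vs log10 M)
    "b_p": RegressionRow(-1.715, 0.182, 0.0, 0.088, 0.032, 0.0),
    # intercept of the phytoplankton biomass spectrum
    "a_p": RegressionRow(8.087, 0.554, 0.0, 0.258, 0.093, 0.0),
    # log10 median-production cell mass (pg C)
    "m_p50": RegressionRow(-0.545, 0.864, -0.078, 0.344, 0.116, 0.006),
    # log10 mass range covering the central 80% of production
    "m_p1090": RegressionRow(0.266, 0.0, 0.025, 0.097, 0.0, 0.006),
}

# --- sampled macro-model parameters (mean, sd) -----------------------------
EPS_P_MEAN, EPS_P_SD = -0.665, 0.087  # log10 TE to primary consumers
EPS_S_MEAN, EPS_S_SD = -0.936, 0.170  # log10 TE to secondary consumers
MU_P_MEAN, MU_P_SD = 3.0, 0.35  # log10 realised PPMR, primary consumers
MU_S_MEAN, MU_S_SD = 3.0, 0.72  # log10 realised PPMR, secondary consumers
R_MEAN, R_SD = 0.755, 0.003  # production-mass scaling exponent

# default correlation between PPMR and TE draws ("weak covariance")
RHO_PPMR_TE = -0.2

# --- fixed constants -------------------------------------------------------
C1 = 25.22  # constant of the individual-production relation
E_ACTIVATION = 0.6  # activation energy of metabolism, eV
K_BOLTZMANN = 8.62e-5  # Boltzmann's constant, eV K-1

PHI_LD = 0.74  # large-phytoplankton grazing to detritus at 0 degC
PHI_SD = 0.14  # small-phytoplankton grazing to detritus at 0 degC
K_D = -0.032  # temperature dependence of the export term, degC-1
R_B = 0.0228  # fraction of production as mineral-protected detritus
D_REMIN = 0.4  # detritus removal rate constant, d-1
S_SINK = 100.0  # detritus sinking rate, m d-1

M_REF_SMALL_PG = 12.9  # 5 um ESD cell mass, pg C: small/large split
REF_EXPORT_DEPTH_M = 200.0  # reference depth for the export multiplier
EUPHOTIC_CAP_M = 180.0  # validity limit of the euphotic-depth polynomial

# carbon <-> wet mass: C(g) = 0.32 * M_dry(g), M_dry(g) = 0.11 * M_wet(g)
CARBON_PER_DRY = 0.32
DRY_PER_WET = 0.11
CARBON_PER_WET = CARBON_PER_DRY * DRY_PER_WET  # 0.0352 g C per g wet

DAYS_PER_YEAR = 365.0
KELVIN_OFFSET = 273.0  # T_K = T_C + 273 as used throughout

OCEAN_VOLUME_KM3 = 1335e6  # volume of the global oceans
SEAWATER_TONNES_PER_M3 = 1.0  # consumer tissue density assumption


def wet_from_carbon(mass_c: float) -> float:
    """Convert a carbon mass to wet mass (same units)."""
    return mass_c / CARBON_PER_WET


def carbon_from_wet(mass_wet: float) -> float:
    """Convert a wet mass to carbon mass (same units)."""
    return mass_wet * CARBON_PER_WET
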