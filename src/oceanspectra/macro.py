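"""Equilibrium macroecological consumer size-spectrum for one cell.

Given one forcing cell and one realisation of the sampled parameters, the
model chains:

1. phytoplankton size structure from (P_P, T_C) regressions;
2. particle-export ratio and the relative-export multiplier tau_r;
3. energy entering the consumer food web: primary-consumer production
   10**eps_p * P_P * tau_r (g C m-2 d-1), annualised and converted from
   carbon to wet mass;
4. an anchor point on the spectrum: that production is assigned to primary
   consumers at wet mass corresponding to m_p50 * 10**mu_p (pg C), and
   converted to biomass by dividing by the temperature- and mass-dependent
   specific production rate P/M = exp(c1 - E/(k T_K)) M**(r-1);
5. the biomass-spectrum slope b_c = eps_s / mu_s + (1 - r): production
   declines by the secondary-consumer transfer efficiency for every
   realised predator-prey log-mass step, and division by the specific
   production rate contributes the (1 - r) term;
6. per-bin biomass, production and abundance on a 0.1 log10 wet-mass grid.

All outputs are depth-integrated, per m2 of sea surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .constants import PHYTO_REGRESSIONS, RegressionRow
from .forcing import EnvCell, analysis_depth
from .phyto import (
    DegenerateDrawError,
    export_state,
    extend_tails,
    phyto_regressions,
)

__all__ = [
    "MacroDraw",
    "SizeSpectrumResult",
    "specific_production",
    "spectrum_slope",
    "anchor_biomass",
    "build_spectrum",
    "tissue_volume",
]


@dataclass(frozen=True)
class MacroDraw:
    """One realisation of the sampled macro-model parameters.

    Transfer efficiencies and predator-prey mass ratios are on log10
    scales; ``phyto_coeffs`` carries one realisation of each regression
    row. Defaults are the distribution means, so ``MacroDraw()`` is the
    deterministic mean-parameter model.
    """

    eps_p: float = K.EPS_P_MEAN
    eps_s: float = K.EPS_S_MEAN
    mu_p: float = K.MU_P_MEAN
    mu_s: float = K.MU_S_MEAN
    r: float = K.R_MEAN
    phyto_coeffs: dict[str, RegressionRow] = field(
        default_factory=lambda: dict(PHYTO_REGRESSIONS)
    )


@dataclass
class SizeSpectrumResult:
    """Consumer spectrum on a 0.1-log10 wet-mass grid (per m2).

    ``edges`` are log10 wet-mass bin edges; ``n``, ``b``, ``p`` are per-bin
    abundance (ind m-2), biomass (g m-2) and production (g m-2 yr-1).
    """

    edges: np.ndarray  # log10 g, len nbins+1
    n: np.ndarray
    b: np.ndarray
    p: np.ndarray
    b_c: float  # biomass-spectrum slope
    a_c: float  # intercept (log10 g m-2 per 0.1-log bin at log10 M = 0)

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def range_totals(self, lo: float, hi: float) -> tuple[float, float, float]:
        """Total (B, P, N) over log10-mass range [lo, hi]."""
        sel = (self.centres >= lo) & (self.centres <= hi)
        return float(self.b[sel].sum()), float(self.p[sel].sum()), float(self.n[sel].sum())


def specific_production(
    m: float | np.ndarray,
    t_c: float,
    r: float = K.R_MEAN,
    c1: float = K.C1,
    e_act: float = K.E_ACTIVATION,
    k_b: float = K.K_BOLTZMANN,
) -> float | np.ndarray:
    """Individual specific production rate P/M (yr-1) at wet mass m (g).

    exp(c1 - E/(k T_K)) * M**(r-1) with T_K = T_C + 273; the constant c1
    is fitted so the rate is per year.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    t_k = t_c + K.KELVIN_OFFSET
    rate = np.exp(c1 - e_act / (k_b * t_k)) * m ** (r - 1.0)
    return float(rate) if rate.ndim == 0 else rate


def spectrum_slope(eps_s: float, mu_s: float, r: float) -> float:
    """Consumer biomass-spectrum slope b_c = eps_s/mu_s + (1 - r).

    eps_s (log10 transfer efficiency) and mu_s (log10 PPMR) are both
    already logarithmic, so their ratio is the log-log decay of production
    with mass; b_s = 1 - r is the slope in the lossless-transfer limit
    (eps_s = 0), where production is flat and biomass rises as M**(1-r)
    through the specific production rate.
    """
    if mu_s == 0:
        raise ValueError("mu_s must be nonzero")
    return eps_s / mu_s + (1.0 - r)


def anchor_biomass(
    pp: float,
    eps_p: float,
    tau_r: float,
    m_p50: float,
    mu_p: float,
    t_c: float,
    r: float = K.R_MEAN,
) -> tuple[float, float]:
    """Anchor point of the consumer spectrum: (wet mass g, biomass g m-2).

    Primary-consumer production is 10**eps_p * P_P * tau_r (g C m-2 d-1),
    annualised and converted carbon -> wet. It is attributed to primary
    consumers at wet mass equivalent to m_p50 * 10**mu_p pg C, and
    converted to biomass by dividing by the specific production rate at
    that mass and temperature.
    """
    prod_c_daily = 10.0**eps_p * pp * tau_r  # g C m-2 d-1
    prod_wet_annual = K.wet_from_carbon(prod_c_daily * K.DAYS_PER_YEAR)
    anchor_mass_c_g = m_p50 * 10.0**mu_p * 1e-12  # pg C -> g C
    anchor_mass_wet = K.wet_from_carbon(anchor_mass_c_g)
    if not (np.isfinite(anchor_mass_wet) and anchor_mass_wet > 0):
        raise DegenerateDrawError("non-finite or non-positive anchor mass")
    b = prod_wet_annual / specific_production(anchor_mass_wet, t_c, r)
    if not np.isfinite(b):
        raise DegenerateDrawError("non-finite anchor biomass")
    return float(anchor_mass_wet), float(b)


def build_spectrum(
    cell: EnvCell,
    draw: MacroDraw | None = None,
    mass_range: tuple[float, float] = (0.0, 6.0),
    bin_width: float = 0.1,
    z_analysis: float | None = None,
) -> SizeSpectrumResult:
    """Build the full per-bin consumer spectrum for one cell and draw.

    ``mass_range`` is in log10 wet grams (default 1 g to 1e6 g; extend the
    lower bound to -5 for microscopic consumers). ``z_analysis`` overrides
    the cell's analysis depth (e.g. a fixed euphotic depth for response-
    surface plots).
    """
    draw = draw or MacroDraw()
    spec = extend_tails(phyto_regressions(cell.pp, cell.sst_c, draw.phyto_coeffs))
    z = analysis_depth(cell) if z_analysis is None else z_analysis
    exp_state = export_state(spec, cell.sst_c, z)
    anchor_m, anchor_b = anchor_biomass(
        cell.pp, draw.eps_p, exp_state.tau_r, spec.m_p50, draw.mu_p, cell.sst_c, draw.r
    )
    b_c = spectrum_slope(draw.eps_s, draw.mu_s, draw.r)
    a_c = np.log10(anchor_b) - b_c * np.log10(anchor_m)

    lo, hi = mass_range
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    m = 10.0**centres
    with np.errstate(over="ignore"):
        b = 10.0 ** (a_c + b_c * centres)
        p = b * specific_production(m, cell.sst_c, draw.r)
    n = b / m
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(p))):
        # draws with near-zero PPMR produce astronomically steep slopes
        raise DegenerateDrawError("non-finite spectrum from extreme slope draw")
    return SizeSpectrumResult(edges=edges, n=n, b=b, p=p, b_c=float(b_c), a_c=float(a_c))


def tissue_volume(
    biomass_tonnes: float,
    ocean_volume_km3: float = K.OCEAN_VOLUME_KM3,
) -> tuple[float, float]:
    """Consumer tissue volume (km3) and the ocean-to-tissue volume ratio.

    Assumes consumer tissue has the density of seawater (1 t = 1 m3), so
    biomass in tonnes maps directly to volume; the ratio expresses how
    dilute macroscopic animal life is in the global ocean.
    """
    if biomass_tonnes < 0:
        raise ValueError("biomass must be non-negative")
    volume_km3 = biomass_tonnes * K.SEAWATER_TONNES_PER_M3 * 1e-9
    ratio = np.inf if volume_km3 == 0 else ocean_volume_km3 / volume_km3
    return float(volume_km3), float(ratio)
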