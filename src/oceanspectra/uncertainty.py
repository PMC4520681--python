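"""Monte-Carlo propagation of parameter uncertainty through the macro model.

Sampled quantities are the four phytoplankton regression coefficient rows
and the five food-web parameters (log10 transfer efficiencies eps_p and
eps_s, log10 predator-prey mass ratios mu_p and mu_s, and the production
scaling exponent r). Draws are normal, with a configurable negative
correlation between each (PPMR, TE) pair — higher mass ratios tend to go
with lower transfer efficiency — and optional within-equation coefficient
correlation. Each draw is pushed through the full cell model; summaries
are percentile envelopes of total biomass and production over requested
mass ranges, plus the spectrum slope.

Regional and global totals apply ONE shared parameter draw to all cells in
each iteration by default: parameter uncertainty is systematic (a shared
property of the food-web parameterisation), not independent cell-level
noise, and only shared draws preserve the full width of the parameter
envelope in aggregated totals. An independent-draw mode is provided for
comparison; it produces narrower intervals by averaging draws out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as K
from .constants import PHYTO_REGRESSIONS, RegressionRow
from .forcing import EnvCell
from .macro import MacroDraw, build_spectrum
from .phyto import DegenerateDrawError

__all__ = [
    "ParamDistributions",
    "PercentileSummary",
    "CellRunResult",
    "draw_params",
    "run_cell",
    "global_aggregate",
    "DEFAULT_PERCENTILES",
    "DEFAULT_RANGES",
]

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)
#: default log10 wet-mass ranges: the full consumer span 1 g - 1e6 g and
#: the fish-and-squid-dominated 100 g - 10 kg window
DEFAULT_RANGES = ((0.0, 6.0), (2.0, 4.0))


@dataclass(frozen=True)
class ParamDistributions:
    """Means, s.d.s and correlations of all sampled macro parameters."""

    eps_p: tuple[float, float] = (K.EPS_P_MEAN, K.EPS_P_SD)
    eps_s: tuple[float, float] = (K.EPS_S_MEAN, K.EPS_S_SD)
    mu_p: tuple[float, float] = (K.MU_P_MEAN, K.MU_P_SD)
    mu_s: tuple[float, float] = (K.MU_S_MEAN, K.MU_S_SD)
    r: tuple[float, float] = (K.R_MEAN, K.R_SD)
    rho_primary: float = K.RHO_PPMR_TE  # corr(mu_p, eps_p)
    rho_secondary: float = K.RHO_PPMR_TE  # corr(mu_s, eps_s)
    phyto_coeffs: dict[str, RegressionRow] = field(
        default_factory=lambda: dict(PHYTO_REGRESSIONS)
    )

    def fixed_at_means(self, *, keep: tuple[str, ...] = ()) -> "ParamDistributions":
        """Copy with all s.d.s zeroed except the named parameters.

        Used for fix-at-mean uncertainty attribution: the share of output
        spread retained when only ``keep`` still varies.
        """
        def z(pair):
            return (pair[0], 0.0)

        coeffs = {
            k: (
                row
                if k in keep
                else RegressionRow(row.alpha, row.beta1, row.beta2)
            )
            for k, row in self.phyto_coeffs.items()
        }
        return ParamDistributions(
            eps_p=self.eps_p if "eps_p" in keep else z(self.eps_p),
            eps_s=self.eps_s if "eps_s" in keep else z(self.eps_s),
            mu_p=self.mu_p if "mu_p" in keep else z(self.mu_p),
            mu_s=self.mu_s if "mu_s" in keep else z(self.mu_s),
            r=self.r if "r" in keep else z(self.r),
            rho_primary=self.rho_primary,
            rho_secondary=self.rho_secondary,
            phyto_coeffs=coeffs,
        )


@dataclass
class PercentileSummary:
    """Percentiles of one output quantity across effective draws."""

    percentiles: dict[float, float]
    n_effective: int
    n_degenerate: int

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        n_degenerate: int,
        qs: tuple[float, ...] = DEFAULT_PERCENTILES,
    ) -> "PercentileSummary":
        # linear interpolation between order statistics
        vals = np.percentile(samples, qs, method="linear")
        return cls(
            percentiles=dict(zip(qs, map(float, vals))),
            n_effective=int(samples.size),
            n_degenerate=n_degenerate,
        )


@dataclass
class CellRunResult:
    """Per-cell Monte-Carlo result: per-draw outputs plus summaries.

    ``biomass``/``production`` map a mass range to the vector of per-draw
    totals (g m-2 and g m-2 yr-1); ``slope`` holds the per-draw spectrum
    slopes. Summaries are percentile envelopes over effective draws.
    """

    biomass: dict[tuple[float, float], np.ndarray]
    production: dict[tuple[float, float], np.ndarray]
    slope: np.ndarray
    n_degenerate: int

    def summary(
        self, qs: tuple[float, ...] = DEFAULT_PERCENTILES
    ) -> dict[str, dict[tuple[float, float], PercentileSummary] | PercentileSummary]:
        return {
            "biomass": {
                rng: PercentileSummary.from_samples(v, self.n_degenerate, qs)
                for rng, v in self.biomass.items()
            },
            "production": {
                rng: PercentileSummary.from_samples(v, self.n_degenerate, qs)
                for rng, v in self.production.items()
            },
            "slope": PercentileSummary.from_samples(self.slope, self.n_degenerate, qs),
        }


def _correlated_pair(
    rng: np.random.Generator, n: int, a: tuple[float, float], b: tuple[float, float], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    ma, sa = a
    mb, sb = b
    if not -1.0 <= rho <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    cov = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
    draws = rng.multivariate_normal([ma, mb], cov, size=n, method="svd")
    return draws[:, 0], draws[:, 1]


def draw_params(dists: ParamDistributions, n: int, seed: int) -> list[MacroDraw]:
    """Draw ``n`` parameter realisations, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    eps_p, mu_p = _correlated_pair(rng, n, dists.eps_p, dists.mu_p, dists.rho_primary)
    eps_s, mu_s = _correlated_pair(rng, n, dists.eps_s, dists.mu_s, dists.rho_secondary)
    r = rng.normal(dists.r[0], dists.r[1], n)
    coeff_draws: dict[str, np.ndarray] = {}
    for name, row in dists.phyto_coeffs.items():
        coeff_draws[name] = np.column_stack(
            [
                rng.normal(row.alpha, row.sd_alpha, n),
                rng.normal(row.beta1, row.sd_beta1, n),
                rng.normal(row.beta2, row.sd_beta2, n),
            ]
        )
    draws = []
    for i in range(n):
        coeffs = {
            name: RegressionRow(*coeff_draws[name][i]) for name in dists.phyto_coeffs
        }
        draws.append(
            MacroDraw(
                eps_p=float(eps_p[i]),
                eps_s=float(eps_s[i]),
                mu_p=float(mu_p[i]),
                mu_s=float(mu_s[i]),
                r=float(r[i]),
                phyto_coeffs=coeffs,
            )
        )
    return draws


def _evaluate_draws(
    cell: EnvCell,
    draws: list[MacroDraw],
    ranges: tuple[tuple[float, float], ...],
    mass_range: tuple[float, float],
) -> tuple[dict, dict, list[float], list[bool]]:
    biomass = {rng_: [] for rng_ in ranges}
    production = {rng_: [] for rng_ in ranges}
    slopes: list[float] = []
    ok: list[bool] = []
    for draw in draws:
        try:
            res = build_spectrum(cell, draw, mass_range=mass_range)
        except DegenerateDrawError:
            ok.append(False)
            continue
        ok.append(True)
        for rng_ in ranges:
            b, p, _ = res.range_totals(*rng_)
            biomass[rng_].append(b)
            production[rng_].append(p)
        slopes.append(res.b_c)
    return biomass, production, slopes, ok


def run_cell(
    cell: EnvCell,
    dists: ParamDistributions | None = None,
    n: int = 10_000,
    seed: int = 0,
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES,
    mass_range: tuple[float, float] | None = None,
) -> CellRunResult:
    """Monte-Carlo run of the macro model for one cell.

    Degenerate draws (unusable phytoplankton spectra) are excluded, not
    resampled, and counted; more than 50% degenerate raises an error
    naming the cell.
    """
    dists = dists or ParamDistributions()
    full = mass_range or (
        min(r[0] for r in ranges),
        max(r[1] for r in ranges),
    )
    draws = draw_params(dists, n, seed)
    biomass, production, slopes, ok = _evaluate_draws(cell, draws, ranges, full)
    n_bad = ok.count(False)
    if n_bad > 0.5 * n:
        raise RuntimeError(
            f"more than half of the draws are degenerate for cell "
            f"region={cell.region} (pp={cell.pp:.3g}, sst={cell.sst_c:.3g})"
        )
    return CellRunResult(
        biomass={k: np.asarray(v) for k, v in biomass.items()},
        production={k: np.asarray(v) for k, v in production.items()},
        slope=np.asarray(slopes),
        n_degenerate=n_bad,
    )


def global_aggregate(
    cells: list[EnvCell],
    dists: ParamDistributions | None = None,
    n: int = 10_000,
    seed: int = 0,
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES,
    shared_draws: bool = True,
) -> CellRunResult:
    """Area-weighted totals across cells, as per-draw vectors (tonnes).

    With ``shared_draws`` (default) every iteration applies one parameter
    draw to all cells, so the global totals inherit the full parameter
    spread; with independent draws each cell receives its own realisation
    per iteration and cell-level spread partly cancels in the sum. A cell
    areal biomass of 1 g m-2 over 1 km2 is exactly 1 tonne, so totals are
    sums of B (g m-2) x area (km2).
    """
    if not cells:
        raise ValueError("empty cell set")
    dists = dists or ParamDistributions()
    full = (min(r[0] for r in ranges), max(r[1] for r in ranges))
    if shared_draws:
        draws = draw_params(dists, n, seed)  # one draw set for all cells
        per_cell = [_evaluate_draws(cell, draws, ranges, full) for cell in cells]
        ok_all = np.all([pc[3] for pc in per_cell], axis=0)
    else:
        per_cell = []
        child_seeds = np.random.SeedSequence(seed).spawn(len(cells))
        for cell, ss in zip(cells, child_seeds):
            draws = draw_params(dists, n, int(ss.generate_state(1)[0] % 2**31))
            per_cell.append(_evaluate_draws(cell, draws, ranges, full))
        ok_all = np.all([pc[3] for pc in per_cell], axis=0)

    n_bad = int((~ok_all).sum())
    if n_bad > 0.5 * n:
        raise RuntimeError("more than half of the iterations are degenerate globally")

    biomass: dict[tuple[float, float], np.ndarray] = {}
    production: dict[tuple[float, float], np.ndarray] = {}
    slopes = np.zeros(int(ok_all.sum()))
    for rng_ in ranges:
        tot_b = np.zeros(int(ok_all.sum()))
        tot_p = np.zeros(int(ok_all.sum()))
        for cell, (bio, prod, slp, ok) in zip(cells, per_cell):
            ok = np.asarray(ok)
            keep = ok_all[ok]  # per-cell effective draws surviving globally
            tot_b += np.asarray(bio[rng_])[keep] * cell.area
            tot_p += np.asarray(prod[rng_])[keep] * cell.area
        biomass[rng_] = tot_b
        production[rng_] = tot_p
    # slope is a per-draw community property, identical across cells only
    # in shared mode; report the area-weighted mean across cells otherwise
    area = np.array([c.area for c in cells])
    slope_stack = []
    for cell, (_, _, slp, ok) in zip(cells, per_cell):
        ok = np.asarray(ok)
        slope_stack.append(np.asarray(slp)[ok_all[ok]])
    slopes = np.average(np.column_stack(slope_stack), axis=1, weights=area)
    return CellRunResult(
        biomass=biomass, production=production, slope=slopes, n_degenerate=n_bad
    )
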