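"""End-to-end orchestration: tidy result tables for whole forcing sets.

Two reports mirror the headline outputs of the modelling chain:

* the macro report — per-region and global percentile tables of consumer
  biomass and production over the standard mass ranges, from Monte-Carlo
  runs of the macroecological model, plus a cumulative biomass-vs-area
  curve and an optional (T, P_P) response surface;
* the fishing report — the MMSY matrix (scenario x baseline percentile x
  size class) and yield curves from the calibrated trait model.

Everything returns pandas DataFrames; writing them to CSV is left to the
caller (or the CLI). Each table carries the seed and configuration used
in ``DataFrame.attrs`` so results are traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forcing import EnvCell
from .macro import MacroDraw, build_spectrum
from .trait import TraitParams
from .uncertainty import (
    DEFAULT_PERCENTILES,
    DEFAULT_RANGES,
    ParamDistributions,
    global_aggregate,
    run_cell,
)
from .fisheries import SCENARIOS, calibrate_resource, yield_curve, aggregate_yields

__all__ = [
    "RunConfig",
    "run_macro_report",
    "cumulative_biomass_curve",
    "response_surface",
    "run_fishing_report",
]


@dataclass
class RunConfig:
    """Configuration shared by the report entry points."""

    seed: int = 0
    n_draws: int = 10_000
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    scenarios: tuple[str, ...] = ("A", "B", "C", "D")
    baseline_percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)
    dists: ParamDistributions = field(default_factory=ParamDistributions)


def _summary_rows(region, result, ranges, percentiles, area):
    rows = []
    summ = result.summary(tuple(percentiles))
    for rng in ranges:
        for quantity, per_range in (("biomass", summ["biomass"]), ("production", summ["production"])):
            ps = per_range[rng]
            for q, v in ps.percentiles.items():
                rows.append(
                    {
                        "region": region,
                        "mass_range": f"{rng[0]:g}-{rng[1]:g}",
                        "quantity": quantity,
                        "percentile": q,
                        "value": v,
                        "area_km2": area,
                        "n_effective": ps.n_effective,
                        "n_degenerate": ps.n_degenerate,
                    }
                )
    return rows


def run_macro_report(cells: Sequence[EnvCell], config: RunConfig | None = None) -> pd.DataFrame:
    """Percentile tables of B and P per region plus a global row.

    Per-region and global values are area-weighted totals (tonnes; a
    cell's 1 g m-2 over 1 km2 is 1 t) with one shared parameter draw per
    Monte-Carlo iteration across all cells of the region/globe.
    """
    config = config or RunConfig()
    if not cells:
        raise ValueError("no forcing cells supplied")
    regions: dict[str, list[EnvCell]] = {}
    for c in cells:
        regions.setdefault(c.region, []).append(c)
    rows = []
    for region, rcells in sorted(regions.items()):
        res = global_aggregate(
            rcells, config.dists, n=config.n_draws, seed=config.seed, ranges=config.ranges
        )
        rows += _summary_rows(region, res, config.ranges, config.percentiles, sum(c.area for c in rcells))
    res = global_aggregate(
        list(cells), config.dists, n=config.n_draws, seed=config.seed, ranges=config.ranges
    )
    rows += _summary_rows("GLOBAL", res, config.ranges, config.percentiles, sum(c.area for c in cells))
    df = pd.DataFrame(rows)
    df.attrs["seed"] = config.seed
    df.attrs["n_draws"] = config.n_draws
    return df


def cumulative_biomass_curve(
    cells: Sequence[EnvCell],
    draw: MacroDraw | None = None,
    mass_range: tuple[float, float] = (0.0, 6.0),
) -> pd.DataFrame:
    """Cumulative biomass fraction vs cumulative area fraction.

    Cells are ranked by areal biomass density (highest first); the curve
    shows how concentrated consumer biomass is in a small share of ocean
    area. Computed at a single parameter draw (default: the means).
    """
    draw = draw or MacroDraw()
    dens, areas, ssts = [], [], []
    for c in cells:
        b, _, _ = build_spectrum(c, draw, mass_range=mass_range).range_totals(*mass_range)
        dens.append(b)
        areas.append(c.area)
        ssts.append(c.sst_c)
    df = pd.DataFrame({"density": dens, "area": areas, "sst_c": ssts})
    df = df.sort_values("density", ascending=False, ignore_index=True)
    total_b = (df.density * df.area).sum()
    df["cum_area_frac"] = df.area.cumsum() / df.area.sum()
    df["cum_biomass_frac"] = (df.density * df.area).cumsum() / total_b
    return df


def response_surface(
    t_grid: np.ndarray,
    pp_grid: np.ndarray,
    draw: MacroDraw | None = None,
    mass_range: tuple[float, float] = (0.0, 6.0),
    z_analysis: float = 50.0,
    ref_depth_m: float = 200.0,
) -> pd.DataFrame:
    """Consumer B and P on a (T, P_P) parameter grid at fixed depths.

    Uses a fixed euphotic/analysis depth so the surface isolates the
    temperature and primary-production response (the convention of the
    headline response-surface figure: analysis depth 50 m).
    """
    draw = draw or MacroDraw()
    rows = []
    for t in np.asarray(t_grid, dtype=float):
        for pp in np.asarray(pp_grid, dtype=float):
            cell = EnvCell(pp=pp, sst_c=t, chl=1.0, mld=0.0, bottom=1e4)
            res = build_spectrum(cell, draw, mass_range=mass_range, z_analysis=z_analysis)
            b, p, _ = res.range_totals(*mass_range)
            rows.append({"sst_c": t, "pp": pp, "biomass": b, "production": p})
    return pd.DataFrame(rows)


def run_fishing_report(
    cells: Sequence[EnvCell],
    config: RunConfig | None = None,
    params: TraitParams | None = None,
    multipliers: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MMSY matrix and yield curves for the calibrated trait model.

    For each region (represented by its area-weighted mean cell), the
    macro model provides the baseline slope/biomass percentiles; the
    trait model is calibrated to each baseline percentile and swept over
    the scenarios and F multipliers. Returns ``(mmsy_table, curves)``:
    the first in the shape scenario x percentile x size class (tonnes
    per year, regions summed), the second the tidy per-region curves.
    """
    config = config or RunConfig()
    regions: dict[str, list[EnvCell]] = {}
    for c in cells:
        regions.setdefault(c.region, []).append(c)

    curve_rows = []
    per_scenario_percentile: dict[tuple[str, float], list] = {}
    for region, rcells in sorted(regions.items()):
        area = sum(c.area for c in rcells)
        # representative cell: area-weighted mean forcing of the region
        w = np.array([c.area for c in rcells]); w = w / w.sum()
        rep = EnvCell(
            pp=float(sum(c.pp * wi for c, wi in zip(rcells, w))),
            sst_c=float(sum(c.sst_c * wi for c, wi in zip(rcells, w))),
            chl=float(sum(c.chl * wi for c, wi in zip(rcells, w))),
            mld=float(sum(c.mld * wi for c, wi in zip(rcells, w))),
            bottom=float(sum(c.bottom * wi for c, wi in zip(rcells, w))),
            area=area,
            region=region,
            region_class=rcells[0].region_class,
        )
        mc = run_cell(rep, config.dists, n=config.n_draws, seed=config.seed)
        for pq in config.baseline_percentiles:
            b_base = float(np.percentile(mc.biomass[(2.0, 4.0)], pq))
            s_base = float(np.percentile(mc.slope, pq))
            cal = calibrate_resource(rep, s_base, b_base, params)
            for sc in config.scenarios:
                yc = yield_curve(rep, sc, cal.params, multipliers=multipliers)
                per_scenario_percentile.setdefault((sc, pq), []).append(yc)
                for k, arr in yc.yields.items():
                    for m, y in zip(yc.multipliers, arr):
                        curve_rows.append(
                            {
                                "region": region,
                                "scenario": sc,
                                "baseline_percentile": pq,
                                "multiplier": m,
                                "species_class": k,
                                "yield_g_m2_yr": y,
                                "yield_t_yr": y * area,
                                "calibration_converged": cal.converged,
                            }
                        )

    mmsy_rows = []
    for (sc, pq), curves in sorted(per_scenario_percentile.items()):
        agg = aggregate_yields(curves)
        for k in agg.yields:
            arr = agg.yield_tonnes(k)
            i = int(np.argmax(agg.yields["all"]))  # community MMSY multiplier
            mmsy_rows.append(
                {
                    "scenario": sc,
                    "baseline_percentile": pq,
                    "species_class": k,
                    "mmsy_t_yr": float(np.max(arr)),
                    "yield_at_community_mmsy_t_yr": float(arr[i]),
                    "community_mmsy_multiplier": agg.mmsy_multiplier,
                }
            )
    mmsy = pd.DataFrame(mmsy_rows)
    curves = pd.DataFrame(curve_rows)
    for df in (mmsy, curves):
        df.attrs["seed"] = config.seed
        df.attrs["n_draws"] = config.n_draws
    return mmsy, curves
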