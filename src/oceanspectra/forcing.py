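"""Environmental forcing: cells, validation, depths and a synthetic generator.

The models are forced per ocean cell by annual-mean depth-integrated primary
production (g C m-2 d-1), sea surface temperature (degC), column chlorophyll
(mg m-2), mixed-layer and bottom depth (m), sea-surface area (km2) and a
region label (an LME id, or an FAO statistical area outside LMEs). Real
forcing arrives as a delimited table (one row per cell); a seeded synthetic
generator produces cells spanning the realistic temperature / primary
production envelope of the world ocean for testing and desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import EUPHOTIC_CAP_M

__all__ = [
    "EnvCell",
    "Envelope",
    "euphotic_depth",
    "analysis_depth",
    "synth_forcing",
    "cells_to_frame",
    "frame_to_cells",
    "read_forcing",
    "write_forcing",
    "validate_cells",
]

# coefficients of the log10 euphotic depth polynomial in x = log10 Chl
_ZE_COEFFS = (2.1236, 0.9325, -1.4264, 0.5278, -0.0762)

#: default synthetic chlorophyll relation Chl = c * P_P**0.8, with c chosen
#: so that Chl = 1 mg m-2 at P_P = 0.25 g C m-2 d-1. The relation the
#: original forcing fields obeyed is not published; this monotone stand-in
#: is a configuration hook, not an empirical fit.
CHL_EXPONENT = 0.8
CHL_COEFF = 0.25 ** -CHL_EXPONENT

SST_VALID_RANGE = (-3.0, 35.0)


@dataclass
class EnvCell:
    """One forcing cell (annual means, depth-integrated quantities)."""

    pp: float  # primary production, g C m-2 d-1
    sst_c: float  # sea surface temperature, degC
    chl: float  # column chlorophyll, mg m-2
    mld: float  # mixed layer depth, m
    bottom: float  # bottom depth, m
    area: float = 1.0  # km2
    region: str = "R0"  # LME or FAO label
    region_class: str = "LME"  # "LME" or "FAO"
    lon: float | None = None
    lat: float | None = None

    def validate(self) -> list[str]:
        """Return a list of problems; empty means the cell is acceptable.

        Hard violations (non-positive production, area or bottom depth,
        negative mixed layer) are errors; an SST outside the plausible
        ocean range is flagged but tolerated.
        """
        problems = []
        if not self.pp > 0:
            problems.append(f"pp must be > 0, got {self.pp}")
        if not self.chl > 0:
            problems.append(f"chl must be > 0, got {self.chl}")
        if not self.area > 0:
            problems.append(f"area must be > 0, got {self.area}")
        if not self.bottom > 0:
            problems.append(f"bottom must be > 0, got {self.bottom}")
        if self.mld < 0:
            problems.append(f"mld must be >= 0, got {self.mld}")
        lo, hi = SST_VALID_RANGE
        if not lo <= self.sst_c <= hi:
            problems.append(f"flag: sst_c {self.sst_c} outside [{lo}, {hi}]")
        return problems


def euphotic_depth(chl: float | np.ndarray) -> float | np.ndarray:
    """Euphotic depth (m) from column chlorophyll (mg m-2).

    A quartic polynomial in log10 chlorophyll, valid to 180 m; deeper
    predictions are clamped to 180 m.
    """
    chl = np.asarray(chl, dtype=float)
    if np.any(chl <= 0):
        raise ValueError("chlorophyll must be positive")
    x = np.log10(chl)
    c0, c1, c2, c3, c4 = _ZE_COEFFS
    log_ze = c0 + c1 * x + c2 * x**2 + c3 * x**3 + c4 * x**4
    ze = np.minimum(10.0**log_ze, EUPHOTIC_CAP_M)
    return float(ze) if ze.ndim == 0 else ze


def analysis_depth(cell: EnvCell) -> float:
    """Depth of the productive layer used for depth integration (m).

    The deeper of the euphotic depth and the mixed layer, additionally
    capped at the bottom depth for shelf cells shallower than either.
    """
    errs = [p for p in cell.validate() if not p.startswith("flag")]
    if errs:
        raise ValueError("; ".join(errs))
    return min(max(euphotic_depth(cell.chl), cell.mld), cell.bottom)


def default_chlorophyll(pp: float | np.ndarray) -> float | np.ndarray:
    """Synthetic column chlorophyll (mg m-2) from primary production."""
    return CHL_COEFF * np.asarray(pp, dtype=float) ** CHL_EXPONENT


@dataclass(frozen=True)
class Envelope:
    """(T, P_P) sampling envelope for the synthetic generator.

    Defaults cover the realistic world-ocean range: SST from -2 to 30 degC
    and primary production from 0.01 to 3 g C m-2 d-1 (sampled uniformly
    in log10).
    """

    t_min: float = -2.0
    t_max: float = 30.0
    pp_min: float = 0.01
    pp_max: float = 3.0


def synth_forcing(
    n_cells: int,
    seed: int,
    envelope: Envelope | None = None,
    *,
    n_regions: int = 4,
    chl_fn=default_chlorophyll,
) -> list[EnvCell]:
    """Generate a reproducible set of synthetic forcing cells.

    Temperature is uniform on [t_min, t_max] and log10 primary production
    uniform on [log10 pp_min, log10 pp_max], jointly covering the envelope.
    Chlorophyll follows the configurable monotone relation ``chl_fn``;
    mixed-layer depths are uniform 10-150 m, bottom depths log-uniform
    100-6000 m (never shallower than the mixed layer) and areas uniform
    1000-4000 km2. Regions are assigned round-robin, alternating LME/FAO.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    env = envelope or Envelope()
    rng = np.random.default_rng(seed)
    sst = rng.uniform(env.t_min, env.t_max, n_cells)
    pp = 10.0 ** rng.uniform(np.log10(env.pp_min), np.log10(env.pp_max), n_cells)
    mld = rng.uniform(10.0, 150.0, n_cells)
    bottom = np.maximum(10.0 ** rng.uniform(2.0, np.log10(6000.0), n_cells), mld + 1.0)
    area = rng.uniform(1000.0, 4000.0, n_cells)
    cells = []
    for i in range(n_cells):
        rid = i % max(n_regions, 1)
        cells.append(
            EnvCell(
                pp=float(pp[i]),
                sst_c=float(sst[i]),
                chl=float(chl_fn(pp[i])),
                mld=float(mld[i]),
                bottom=float(bottom[i]),
                area=float(area[i]),
                region=f"R{rid}",
                region_class="LME" if rid % 2 == 0 else "FAO",
            )
        )
    return cells


_COLUMNS = [
    "pp",
    "sst_c",
    "chl",
    "mld",
    "bottom",
    "area",
    "region",
    "region_class",
    "lon",
    "lat",
]


def cells_to_frame(cells: Iterable[EnvCell]) -> pd.DataFrame:
    """Tabulate cells as a DataFrame (column units documented in I/O docs)."""
    return pd.DataFrame([{k: getattr(c, k) for k in _COLUMNS} for c in cells])


def frame_to_cells(df: pd.DataFrame) -> list[EnvCell]:
    required = {"pp", "sst_c", "chl", "mld", "bottom"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"forcing table missing columns: {sorted(missing)}")
    cells = []
    for _, row in df.iterrows():
        cells.append(
            EnvCell(
                pp=float(row["pp"]),
                sst_c=float(row["sst_c"]),
                chl=float(row["chl"]),
                mld=float(row["mld"]),
                bottom=float(row["bottom"]),
                area=float(row.get("area", 1.0)),
                region=str(row.get("region", "R0")),
                region_class=str(row.get("region_class", "LME")),
                lon=None if pd.isna(row.get("lon")) else float(row.get("lon")),
                lat=None if pd.isna(row.get("lat")) else float(row.get("lat")),
            )
        )
    return cells


def write_forcing(cells: Iterable[EnvCell], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def read_forcing(path: str | Path) -> list[EnvCell]:
    return frame_to_cells(pd.read_csv(path))


def validate_cells(cells: Sequence[EnvCell]) -> dict[int, list[str]]:
    """Validate all cells; returns {cell index: problems} for offenders."""
    report = {}
    for i, c in enumerate(cells):
        probs = c.validate()
        if probs:
            report[i] = probs
    return report
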