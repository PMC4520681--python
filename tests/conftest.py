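"""Shared fixtures: the reference forcing cell, Monte-Carlo baselines from
the macro model, and the calibrated trait model at that cell.

The expensive objects (equilibrium runs, calibrations, yield sweeps) are
session-scoped so the acceptance-style checks and the module tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from oceanspectra.forcing import EnvCell, default_chlorophyll
from oceanspectra.fisheries import calibrate_resource, yield_curve
from oceanspectra.uncertainty import run_cell

#: multiplier grid used for simulation-heavy yield checks (the production
#: grid is 0-3 in steps of 0.05; the checks use a coarser sweep)
COARSE_MULTS = np.round(np.arange(0.0, 3.0001, 0.25), 10)

BASELINE_SEED = 123
BASELINE_DRAWS = 2000


@pytest.fixture(scope="session")
def ref_cell() -> EnvCell:
    """The reference calibration cell: 15 degC, 0.5 g C m-2 d-1."""
    return EnvCell(
        pp=0.5,
        sst_c=15.0,
        chl=float(default_chlorophyll(0.5)),
        mld=50.0,
        bottom=4000.0,
        area=1000.0,
        region="REF",
        region_class="LME",
    )


@pytest.fixture(scope="session")
def macro_mc(ref_cell):
    """Monte-Carlo macro run at the reference cell (seeded)."""
    return run_cell(ref_cell, n=BASELINE_DRAWS, seed=BASELINE_SEED)


@pytest.fixture(scope="session")
def macro_baselines(macro_mc):
    """(slope, biomass over 100 g - 10 kg) at the 25th/50th/75th percentiles."""
    out = {}
    for q in (25.0, 50.0, 75.0):
        out[q] = (
            float(np.percentile(macro_mc.slope, q)),
            float(np.percentile(macro_mc.biomass[(2.0, 4.0)], q)),
        )
    return out


@pytest.fixture(scope="session")
def median_cal(ref_cell, macro_baselines):
    """Trait model calibrated to the median macro baseline."""
    slope, biomass = macro_baselines[50.0]
    return calibrate_resource(ref_cell, slope, biomass)


@pytest.fixture(scope="session")
def curves_ad(ref_cell, median_cal):
    """Coarse-grid yield curves for scenarios A and D at the median."""
    return {
        sc: yield_curve(ref_cell, sc, median_cal.params, multipliers=COARSE_MULTS)
        for sc in ("A", "D")
    }
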