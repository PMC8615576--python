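import numpy as np
import pytest

from ptmcycle import (
    DoseGrid,
    FullParameters,
    MMParameters,
    scan_dose_response,
)


@pytest.fixture(scope="session")
def mm_defaults():
    return MMParameters()


@pytest.fixture(scope="session")
def x_grid():
    return DoseGrid("X", 1e-2, 1e2, 1.0)


@pytest.fixture(scope="session")
def baseline_curve(mm_defaults, x_grid):
    """MM model at default parameters, kinase dose scan with 1% increments."""
    return scan_dose_response(mm_defaults, "mm", x_grid)


@pytest.fixture(scope="session")
def closed_cycle_curve(mm_defaults, x_grid):
    """Classical cycle without synthesis/turnover, conserved total = 100."""
    return scan_dose_response(mm_defaults.with_(k0=0.0, k3=0.0, k4=0.0),
                              "mm", x_grid, total=100.0)


@pytest.fixture(scope="session")
def full_default_curve():
    """Full model at defaults (Ytot=1), kinase dose scan."""
    return scan_dose_response(FullParameters(), "full",
                              DoseGrid("Xtot", 1e-2, 1e2, 1.0))


@pytest.fixture(scope="session")
def stabilized_curve(mm_defaults, x_grid):
    """MM model with the modified form stabilized tenfold (k4=0.001)."""
    return scan_dose_response(mm_defaults.with_(k4=0.001), "mm", x_grid)
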