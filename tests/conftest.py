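"""Shared fixtures: calibrated parameters, reference simulations, coarse scans.

Expensive objects (dose scans, reference trajectories) are session-scoped
so the suite runs each simulation once. Scans use coarser dose grids than
the full analysis; contour interpolation agrees with denser grids to a
few percent, which is well inside the tolerances asserted here.
"""

import numpy as np
import pytest

from jakstat_memory import dosescan, features
from jakstat_memory.model import (
    apply_knockout,
    default_parameters,
    resting_state,
    single_pulse_protocol,
    two_pulse_protocol,
)
from jakstat_memory.simulate import simulate

COARSE_D1 = np.concatenate([np.arange(1.0, 31.0, 2.0), [40.0, 55.0, 70.0, 85.0, 100.0]])
COARSE_D2 = np.unique(np.round(np.logspace(0.0, 2.0, 25), 4))


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def ko_params(params):
    return apply_knockout(params, "PTP")


@pytest.fixture(scope="session")
def rest(params):
    return resting_state(params)


@pytest.fixture(scope="session")
def reference_pulse(params):
    """Single 1 h 100 ng/ml IFN-γ pulse over 14 h."""
    return simulate(params, single_pulse_protocol("IFN-gamma", 100.0, horizon=840.0))


@pytest.fixture(scope="session")
def reference_peak(reference_pulse):
    series = reference_pulse.nuclear_stat1
    return float(series.max() - series[0])


@pytest.fixture(scope="session")
def two_pulse_100_6h(params):
    return simulate(params, two_pulse_protocol("IFN-gamma", 100, "IFN-gamma", 100, 360.0))


@pytest.fixture(scope="session")
def scan_3h(params):
    return dosescan.two_pulse_scan(params, 180.0, doses1=COARSE_D1, doses2=COARSE_D2)


@pytest.fixture(scope="session")
def scan_6h(params):
    return dosescan.two_pulse_scan(params, 360.0, doses1=COARSE_D1, doses2=COARSE_D2)


@pytest.fixture(scope="session")
def scan_6h_ko(ko_params):
    return dosescan.two_pulse_scan(
        ko_params, 360.0, doses1=COARSE_D1[::2], doses2=COARSE_D2[::2]
    )


@pytest.fixture(scope="session")
def scan_crosstalk(params):
    return dosescan.crosstalk_scan(params, "ab->g", doses1=COARSE_D1, doses2=COARSE_D2)
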