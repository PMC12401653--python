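import numpy as np
import pytest

from toxscreen import (CalPoint, load_reference_panel,
                       load_reference_pt_table)

ALPRAZOLAM_LEVELS = (50.0, 125.0, 250.0, 375.0, 500.0)


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {e.analyte_name: e for e in panel}


@pytest.fixture(scope="session")
def pt_table():
    return load_reference_pt_table()


@pytest.fixture
def exact_line_points():
    """Five calibrators exactly on y = 0.002 x + 0.01."""
    return [CalPoint(x, 0.002 * x + 0.01)
            for x in (100.0, 500.0, 1000.0, 1500.0, 2000.0)]


def noisy_curve(levels, slope, intercept, prop_sd, const_sd, rng):
    """One synthetic calibration curve with mixed-scale Gaussian noise."""
    return [CalPoint(x, slope * x + intercept
                     + rng.normal(0.0, const_sd + prop_sd * x))
            for x in levels]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
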