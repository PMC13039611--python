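import numpy as np
import pytest

from stmrt import ripple_synth as rs
from stmrt import rt_pipeline as rp
from stmrt import trial_sim as ts


@pytest.fixture(scope="session")
def calibration():
    return rs.CalibrationModel()


@pytest.fixture(scope="session")
def broadband_carrier_10s(calibration):
    """Calibrated, accentuated 10 s broadband carrier (no modulation)."""
    spec = rs.broadband_spec(4.0, 0.0)
    return spec, rs.make_accentuated_carrier(spec, calibration, 10.0, seed=1)


@pytest.fixture(scope="session")
def narrowband_carrier_10s(calibration):
    """Calibrated, accentuated 10 s narrowband (1 kHz) carrier."""
    spec = rs.narrowband_spec(1000.0)
    return spec, rs.make_accentuated_carrier(spec, calibration, 10.0, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-participant cohort with the default study conditions."""
    config = ts.CohortConfig(n_participants=5)
    profiles, records = ts.simulate_cohort(config, seed=11)
    return config, profiles, records


@pytest.fixture(scope="session")
def small_cohort_clean(small_cohort):
    _, _, records = small_cohort
    return rp.preprocess(records)
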