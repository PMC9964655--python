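import numpy as np
import pytest

from emgrehab import (
    CalibrationParams,
    ConditionEffect,
    SubjectProfile,
    calibrate,
    filter_raw,
    generate_calibration_recording,
    rectify_rms,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230215)


@pytest.fixture
def profile():
    return SubjectProfile(subject_id=1)


@pytest.fixture
def quiet_profile():
    """Zero resting tone: rest-phase envelope is exactly zero without noise."""
    return SubjectProfile(subject_id=1, rest_level_ed=0.0, rest_level_fds=0.0)


@pytest.fixture
def calib_params(profile):
    """Calibration parameters derived from a clean synthetic calibration."""
    rec = generate_calibration_recording(profile, 42)
    return calibrate(rectify_rms(filter_raw(rec)))


@pytest.fixture
def simple_params():
    return CalibrationParams(mvc_ed=1.0, mvc_fds=1.0, epsilon=0.15, mu=0.15)
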