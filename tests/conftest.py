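import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hemoloop import (
    ControllerConfig,
    PatientParams,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def quiet_patient() -> PatientParams:
    """Default twin with the sensor noise switched off."""
    return PatientParams(noise_sd=0.0)


@pytest.fixture
def default_config() -> ControllerConfig:
    """Controller seeded as calibration would for the default twin
    (kp = 1/gain, Ti = 30 s, amplitude range up to saturation)."""
    return ControllerConfig(kp=0.2, ki=0.2 / 30.0, target=120.0, amp_max=12.0)
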