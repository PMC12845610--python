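import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from coilpilot.head_geometry import HeadLandmarks
from coilpilot.io import reference_trial


@pytest.fixture
def symmetric_landmarks() -> HeadLandmarks:
    """Level, un-rolled head: ears at +-75 mm, nasion straight ahead."""
    return HeadLandmarks(nasion=[0.0, 0.0, 90.0],
                         left_preauricular=[-75.0, 0.0, 0.0],
                         right_preauricular=[75.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def example_trial():
    """The packaged ten-condition tilt-sweep log (reference pitch 25)."""
    return reference_trial()
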