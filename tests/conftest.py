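import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatgain",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatgain")


@pytest.fixture
def rng():
    return np.random.default_rng(20240412)


@pytest.fixture
def tiny_trace():
    """A five-peak repeat trace used by the weighted-mean worked example."""
    from repeatgain.calibration import RepeatTrace

    return RepeatTrace(
        sample_id="tiny",
        repeats=[113, 114, 115, 116, 117],
        heights=[100, 300, 1000, 400, 200],
    )
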