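import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20150521)


@pytest.fixture
def toy_table():
    """4-bait table with the hand-evaluated worked example in column Q."""
    from micoskit.apms import StatsTable

    # prey Q: detected only by bait A (X=9, p=2); prey R: everywhere at 16
    return StatsTable(
        baits=["A", "B", "C", "D"],
        preys=["Q", "R"],
        apsm=[[9, 16], [0, 16], [0, 16], [0, 16]],
        detections=[[2, 2], [0, 2], [0, 2], [0, 2]],
    )
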