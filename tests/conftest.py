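import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trace_csv(tmp_path):
    """A minimal valid three-point trace file."""
    p = tmp_path / "lib1.trace.csv"
    p.write_text("size,density\n100,0\n500,10\n1000,0\n")
    return p
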