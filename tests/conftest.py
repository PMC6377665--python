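import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_betas():
    """Three probes x two samples, hand-enterable values."""
    return pd.DataFrame(
        {"A": [0.2, 0.4, 0.8], "B": [0.1, 0.5, 0.9]},
        index=["cg01", "cg02", "cg03"],
    )


@pytest.fixture
def tiny_weights():
    return pd.DataFrame(
        {"probe_id": ["cg01", "cg02", "cg03"], "effect": [0.5, -1.0, 0.25]}
    )
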