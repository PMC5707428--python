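import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dimer_dataset():
    """Small low-noise dimer fixture shared by sampler-level tests."""
    from dataclasses import replace

    from lj6p.synthetic import generate, argon_presets

    spec = replace(argon_presets()["dimer_Q"], seed=42)
    return generate(spec), spec
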