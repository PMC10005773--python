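import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import slimemetrics as sm

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def clean_helix_spec() -> sm.HelixSpec:
    """Noise-free helix with simple round-number ground truth."""
    return sm.HelixSpec(
        thread_diameter_phi=0.5,
        helical_diameter_D=0.5,
        pitch_P=2.0,
        n_half_loops=10,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def clean_series(clean_helix_spec) -> sm.LandmarkSeries:
    return sm.make_helix_landmarks(clean_helix_spec, dense=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
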