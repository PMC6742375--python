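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

from doublestep import GeneratorConfig, GroupParams
from doublestep.simulate import generate_session


def quiet_groups(**overrides):
    """Single-group parameter set with guaranteed corrections, no contaminants."""
    probs = {(0, "left"): 1.0, (0, "right"): 1.0, (200, "left"): 1.0, (200, "right"): 1.0}
    params = dict(correction_probability=probs)
    params.update(overrides)
    return {"younger": GroupParams(**params)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_config():
    """One participant, deterministic geometry: no noise, offsets or contaminants."""
    return GeneratorConfig(
        participants=(("p1", "younger"),),
        groups=quiet_groups(),
        blocks=1,
        noise_sd=0.0,
        start_offset_sd=0.0,
        artifact_rate=0.0,
        behavioral_outlier_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_session(noiseless_config):
    session, truths = generate_session(noiseless_config, seed=3)
    return session, truths
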