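import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight small synthetic scenes shared by training-related tests."""
    from reflexseg.synthetic import SceneParams, generate_dataset
    samples, _ = generate_dataset(SceneParams(image_size=64, seed=21), 8)
    return samples
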