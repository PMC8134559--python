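import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from pdprobe import (  # noqa: E402
    PhantomSpec,
    SurrogateSpec,
    make_phantom,
    make_surrogate,
    preprocess_image,
)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free phantom: ground-truth mask and labels are exactly recoverable."""
    return make_phantom(PhantomSpec(seed=3, age_months=100.0, noise_sd=0.0))


@pytest.fixture(scope="session")
def prepped(clean_bundle):
    """Full preprocessing of the clean phantom, labels carried through."""
    return preprocess_image(clean_bundle.image, labels=clean_bundle.labels)


@pytest.fixture(scope="session")
def linear_model():
    return make_surrogate(SurrogateSpec("linear", seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
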