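import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phloemflow import PDCensus, PDGeometry, SapProperties, TubeGeometry


@pytest.fixture
def sap():
    return SapProperties()


@pytest.fixture
def tube():
    return TubeGeometry()


@pytest.fixture
def census():
    return PDCensus()


@pytest.fixture
def simple_pd():
    return PDGeometry.simple()


@pytest.fixture
def funnel_pd():
    return PDGeometry.funnel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
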