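import numpy as np
import pytest
from hypothesis import settings

from usvloc import pipeline
from usvloc.geometry import default_scene

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def small_bundle():
    """A 15-call dyadic close-contact scene at 10 dB in-band SNR."""
    return pipeline.simulate(n_usvs=15, seed=11)


@pytest.fixture(scope="session")
def small_run(small_bundle):
    """Full pipeline output on the small bundle."""
    return pipeline.run(small_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
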