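import numpy as np
import pytest

from exponet.exposome import COMPONENTS, ExposureProfile, load_weight_table
from exponet.metrics import load_reference_network


@pytest.fixture(scope="session")
def weights():
    return load_weight_table()


@pytest.fixture(scope="session")
def reference_network():
    return load_reference_network()


def make_profile(present=(), missing=(), paternal_tier=None):
    """Build an ExposureProfile from component name lists."""
    states = {}
    for comp in COMPONENTS:
        if comp in present:
            states[comp] = "present"
        elif comp in missing:
            states[comp] = "missing"
        else:
            states[comp] = "absent"
    if paternal_tier is None:
        paternal_tier = {
            "present": "35-54", "absent": "none", "missing": "missing",
        }[states["advanced_paternal_age"]]
    return ExposureProfile(states=states, paternal_tier=paternal_tier)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240229)
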