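import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from tfcdiff import BinnedDistribution, FractionalParams

hypothesis_settings.register_profile(
    "deterministic", derandomize=True, deadline=None
)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def edges15():
    """The default 15-slot layout over the plausible TFC range."""
    return np.linspace(20.0, 80.0, 16)


@pytest.fixture
def centered_dist(edges15):
    """Unimodal distribution concentrated around the middle slots."""
    m = np.zeros(15)
    m[6], m[7], m[8] = 0.25, 0.6, 0.15
    return BinnedDistribution(slot_edges=edges15, masses=m)


@pytest.fixture
def classical_params():
    return FractionalParams(alpha=1.0, k_alpha=1.0)


@pytest.fixture
def subdiffusive_params():
    return FractionalParams(alpha=0.47, k_alpha=1.0)
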