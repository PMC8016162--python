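import numpy as np
import pytest

from k2ptraj.features import canonical_sf_selection
from k2ptraj.synthetic import SFGeometrySpec, build_filter_coordinates


@pytest.fixture(scope="session")
def sf_selection():
    return canonical_sf_selection()


@pytest.fixture(scope="session")
def filter_traj():
    """Noise-free idealised filter, no flips."""
    return build_filter_coordinates(SFGeometrySpec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
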