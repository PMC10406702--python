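import numpy as np
import pytest

from axsi.library import DiameterGrid
from axsi.phantom import scheme_preset


@pytest.fixture(scope="session")
def hcp_scheme():
    """Full HCP-style scheme (90 directions/shell) for recovery tests."""
    return scheme_preset("hcp")


@pytest.fixture(scope="session")
def small_scheme():
    """Reduced HCP-style scheme for cheap structural tests."""
    return scheme_preset("hcp", n_dirs_per_shell=16, n_b0=2)


@pytest.fixture(scope="session")
def grid():
    return DiameterGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
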