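import numpy as np
import pytest

import acoustopattern as ap


@pytest.fixture(scope="session")
def geometry():
    return ap.device_array()


@pytest.fixture(scope="session")
def ws_central():
    """Workspace on the central 4 mm patterning grid (cheap)."""
    return ap.default_workspace()


@pytest.fixture(scope="session")
def ws_full():
    """Workspace on the full-chamber grid (used by clearing tools)."""
    return ap.default_workspace(full_chamber=True)


@pytest.fixture(scope="session")
def bench1d():
    return ap.TwoStateBench()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
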