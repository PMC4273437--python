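import numpy as np
import pytest

from mbatlas.atlas.records import load_atlas
from mbatlas.phantom import PhantomSpec, make_standard_brain


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def std():
    """Default-scale synthetic standard brain (shared, treat as read-only)."""
    return make_standard_brain()


@pytest.fixture(scope="session")
def small_std():
    """Small standard brain for fast registration/pipeline tests."""
    return make_standard_brain(PhantomSpec(shape=(48, 64, 64)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
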