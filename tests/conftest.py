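import numpy as np
import pytest

from e3pot import toydata
from e3pot.structures import AtomicStructure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def periodic_template():
    return toydata.simple_cubic_structure(n_cells=2, spacing=2.47, z=18)


@pytest.fixture(scope="session")
def labeled_frames(periodic_template):
    """A small labeled dataset from the toy oracle (shared across tests)."""
    return toydata.sample_dataset(periodic_template, 20, displacement=0.15, seed=42)


@pytest.fixture
def random_cluster(rng):
    """A 6-atom two-species cluster with no close contacts."""
    while True:
        pos = rng.normal(size=(6, 3)) * 1.8
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        if d[np.triu_indices(6, 1)].min() > 1.2:
            return AtomicStructure(pos, np.array([1, 1, 8, 1, 8, 1]))
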