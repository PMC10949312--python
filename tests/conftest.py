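import numpy as np
import pytest

from dwmine.superpose import load_reference
from dwmine.synthetic_data import (
    CATALYTIC_QUERY_SPECS,
    build_constellation,
    standard_fixture_set,
)


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def fixture_set():
    """The standard ten-structure mining fixture set with ground truth."""
    return standard_fixture_set()


@pytest.fixture(scope="session")
def catalytic_structure():
    """Cys/Asp/Asp/His constellation at the canonical query geometry."""
    return build_constellation(CATALYTIC_QUERY_SPECS, rng=0, structure_id="query")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
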