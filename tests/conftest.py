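import numpy as np
import pytest

from cosubst.models import StateSpace, build_gtr_model
from cosubst.tree import read_newick


@pytest.fixture
def two_state_model():
    """Symmetric-exchangeability 2-state model with pi = (0.3, 0.7)."""
    space = StateSpace("amino20", ("A", "R"), {"A": "A", "R": "R"})
    return build_gtr_model(
        space, np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0.3, 0.7])
    )


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.3,B:0.5):0.2,(C:0.7,D:0.1):0.4);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
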