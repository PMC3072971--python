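
import numpy as np
import pytest

from spiculevo import SimulationConfig, make_fixture, parse_newick


@pytest.fixture()
def three_tip_tree():
    return parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")


@pytest.fixture(scope="session")
def default_fixture():
    """The packaged desk-scale synthetic dataset (study-shaped sizes)."""
    return make_fixture(SimulationConfig(seed=0))
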