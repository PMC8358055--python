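import networkx as nx
import numpy as np
import pytest

from coevopath import AlignedFamily
from coevopath.synthetic import SyntheticSpec, make_ensemble, make_go_world, make_msa


@pytest.fixture(scope="session")
def toy_family() -> AlignedFamily:
    """Two perfectly coupled columns: A<->C vs V<->W."""
    return AlignedFamily.from_sequences(["AC", "VW"] * 4)


@pytest.fixture(scope="session")
def synthetic_msa():
    spec = SyntheticSpec(seed=11)
    return make_msa(spec)


@pytest.fixture(scope="session")
def synthetic_ensemble():
    spec = SyntheticSpec(seed=13, n_residues=40, n_models=8)
    return make_ensemble(spec)


@pytest.fixture(scope="session")
def go_world():
    spec = SyntheticSpec(seed=17)
    return make_go_world(spec)


@pytest.fixture(scope="session")
def chain_ontology() -> nx.DiGraph:
    """T -is_a-> P -is_a-> R, plus a sibling Q of T under P."""
    g = nx.DiGraph()
    g.add_edge("T", "P", relation="is_a", c_e=0.8)
    g.add_edge("P", "R", relation="is_a", c_e=0.8)
    g.add_edge("Q", "P", relation="is_a", c_e=0.8)
    return g


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
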