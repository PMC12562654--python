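import numpy as np
import pytest

from dynafic.io import EdgeRecord, OntologyDAG
from dynafic.network import integrate_layers


@pytest.fixture
def chain_dag():
    """root <- A <- B plus a separate branch root <- C (all is_a)."""
    return OntologyDAG({
        "root": set(),
        "A": {("root", "is_a")},
        "B": {("A", "is_a")},
        "C": {("root", "is_a")},
    })


@pytest.fixture
def diamond_dag():
    """D reaches the root via paths of length 2 (via A) and 3 (via B <- C)."""
    return OntologyDAG({
        "root": set(),
        "A": {("root", "is_a")},
        "C": {("root", "is_a")},
        "B": {("C", "is_a")},
        "D": {("A", "is_a"), ("B", "is_a")},
    })


def ppi(a, b, w):
    s, t = sorted((a, b))
    return EdgeRecord(s, t, "ppi", w, directed=False)


def go(a, b, w):
    s, t = sorted((a, b))
    return EdgeRecord(s, t, "go", w, directed=False)


def tf(a, b, w=1.0):
    return EdgeRecord(a, b, "tf", w, directed=True)


@pytest.fixture
def two_node_network():
    """Two nodes joined by one unit-weight undirected edge: W = [[0,1],[1,0]]."""
    return integrate_layers([ppi("a", "b", 1.0)], [], [],
                            layer_weights={"ppi": 1.0, "go": 0.5, "tf": 1.5})
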