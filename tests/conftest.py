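import networkx as nx
import numpy as np
import pytest

from disinfosim import GraphSpec, assign_weights, build_graph


@pytest.fixture(scope="session")
def k400():
    """Weighted complete graph on 400 nodes (all weights 1)."""
    return assign_weights(build_graph(GraphSpec(family="complete", n=400)))


@pytest.fixture()
def path3():
    """Path a-b-c as a weighted SocialGraph (nodes 0-1-2)."""
    return assign_weights(nx.path_graph(3))


@pytest.fixture()
def star4():
    """Star with center 0 and 4 leaves."""
    return assign_weights(nx.star_graph(4))
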