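import networkx as nx
import numpy as np
import pytest

from coocnet.network import SignedNetwork
from coocnet.prep import FeatureTable
from coocnet.synth import GroundTruthSpec, make_ground_truth, simulate_counts


def net_from_edges(edges, nodes=None, threshold=0.5) -> SignedNetwork:
    """Build a SignedNetwork from (u, v, weight) triples."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), sign=1 if w > 0 else -1)
    return SignedNetwork(graph=g, threshold=threshold)


@pytest.fixture
def path_net():
    """Unweighted-style path a-b-c-d with positive unit weights."""
    return net_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])


@pytest.fixture
def star_net():
    """Star K1,5 centered on 'hub'."""
    return net_from_edges([("hub", f"leaf{i}", 1.0) for i in range(5)])


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled community used for fast end-to-end tests."""
    return GroundTruthSpec(
        n_taxa=50,
        module_sizes=(12, 9),
        symbiont_partner_count=5,
        contaminant_ids=("g__ContamA", "g__ContamB", "g__ContamC"),
        depth=20_000,
        n_negative_controls=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_table(small_spec):
    truth = make_ground_truth(small_spec)
    return simulate_counts(truth, small_spec), truth


@pytest.fixture
def toy_table():
    """Tiny hand-written table: 4 taxa, 3 real samples + 2 controls."""
    counts = np.array(
        [
            [10, 20, 30, 0, 0],    # normal taxon
            [0, 5, 0, 40, 60],     # control-enriched
            [1, 1, 1, 1, 1],       # ubiquitous low
            [100, 100, 100, 0, 1], # abundant in real samples
        ]
    )
    return FeatureTable(
        taxon_ids=["t1", "t2", "t3", "t4"],
        sample_ids=["s1", "s2", "s3", "nc1", "nc2"],
        counts=counts,
        is_control=np.array([False, False, False, True, True]),
    )
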