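import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from uedamalign import PPINetwork
from uedamalign.birandom_walk import MappingMatrix, WalkParams
from uedamalign.homology import SeedMatrix


def net_from_edges(edges, label="net", extra_nodes=()):
    net = PPINetwork(species_label=label)
    for a, b in edges:
        net.add_edge(a, b)
    for n in extra_nodes:
        net.graph.add_node(n)
    return net


def seed_from_pairs(pairs, proteins1, proteins2):
    """Build a SeedMatrix directly from explicit 0/1 pairs."""
    index1 = {p: i for i, p in enumerate(sorted(proteins1))}
    index2 = {p: i for i, p in enumerate(sorted(proteins2))}
    rows = [index1[a] for a, _ in pairs]
    cols = [index2[b] for _, b in pairs]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(index1), len(index2)))
    return SeedMatrix(A=A, index1=index1, index2=index2)


def mapping_from_scores(scores, proteins1, proteins2, l=2, r=2):
    """Build a MappingMatrix directly from {(p1, p2): score}."""
    index1 = {p: i for i, p in enumerate(sorted(proteins1))}
    index2 = {p: i for i, p in enumerate(sorted(proteins2))}
    R = sp.lil_matrix((len(index1), len(index2)))
    for (a, b), v in scores.items():
        R[index1[a], index2[b]] = v
    return MappingMatrix(R=R.tocsr(), index1=index1, index2=index2,
                         params=WalkParams(l=l, r=r))


@pytest.fixture
def path_pair():
    """Two mirrored path networks with a single seed pair."""
    netP = net_from_edges([("u1", "u2")], "P")
    netH = net_from_edges([("v1", "v2")], "H")
    return netP, netH
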