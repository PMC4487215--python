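"""Subnetwork decomposition of one input network.

The dividing step of dividing-and-matching: one of the two PPI networks
is split into small subnetworks, either by intersecting a catalogue of
known protein complexes with the network, or — when no catalogue is
available — by the bundled minimal Markov clustering (MCL). External
clusterings (core-attachment, maximal-clique, clique-percolation ...)
plug in through the catalogue file format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_io import ComplexCatalogue, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """A protein set carved out of one network, to be matched across."""

    source_network: str
    members: set[str]
    origin: str  # "known_complex" | "cluster"
    label: str = ""


def partition_from_catalogue(cat: ComplexCatalogue, net: PPINetwork) -> list[Subnetwork]:
    """One subnetwork per catalogue complex, intersected with the network.

    Catalogue order is preserved; complexes with no member present in
    the network are dropped with a warning.
    """
    subs: list[Subnetwork] = []
    n_dropped = 0
    for cid, members in cat:
        present = members & net.nodes
        if not present:
            n_dropped += 1
            continue
        subs.append(Subnetwork(source_network=net.species_label, members=present,
                               origin="known_complex", label=cid))
    if n_dropped:
        logger.warning("partition_from_catalogue: %d complexes had no member in "
                       "network %s and were dropped", n_dropped, net.species_label)
    return subs


def mcl_partition(net: PPINetwork, inflation: float = 2.0, max_iter: int = 100,
                  tol: float = 1e-6) -> list[Subnetwork]:
    """Minimal Markov clustering of one PPI network.

    Standard MCL on the column-stochastic adjacency with unit self-loops:
    expansion is matrix squaring, inflation is entrywise power followed
    by column renormalization, repeated until the matrix changes by less
    than ``tol`` (max norm) or ``max_iter`` rounds. Clusters are read off
    the attractor rows of the limit matrix and are non-overlapping.
    Isolated nodes form singleton clusters.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    nodes = sorted(net.nodes)
    if not nodes:
        return []
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)

    rows, cols = [], []
    for a, b in net.graph.edges:
        rows.extend((index[a], index[b]))
        cols.extend((index[b], index[a]))
    rows.extend(range(n))  # self-loops, weight 1 = max incident weight
    cols.extend(range(n))
    M = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).toarray()
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        M[M < 1e-12] = 0.0             # prune numerical dust
        if np.abs(M - prev).max() < tol:
            break

    # attractors: rows with any nonzero; each column's support assigns nodes
    clusters: dict[frozenset, set[str]] = {}
    for j in range(n):
        support = frozenset(np.nonzero(M[:, j] > 1e-9)[0])
        if not support:
            support = frozenset({j})
        clusters.setdefault(support, set()).add(nodes[j])
    # merge overlapping attractor systems (rare ties) so clusters are disjoint
    merged: list[set[str]] = []
    owner: dict[frozenset, int] = {}
    sys_of: dict[int, set[int]] = {}
    for support, members in clusters.items():
        hit = [k for k, s in sys_of.items() if s & set(support)]
        if hit:
            k0 = hit[0]
            for k in hit[1:]:
                merged[k0] |= merged[k]
                sys_of[k0] |= sys_of[k]
                merged[k] = set()
                sys_of[k] = set()
            merged[k0] |= members
            sys_of[k0] |= set(support)
        else:
            sys_of[len(merged)] = set(support)
            merged.append(set(members))

    out = [Subnetwork(source_network=net.species_label, members=c,
                      origin="cluster", label=f"mcl{i+1}")
           for i, c in enumerate(sorted((c for c in merged if c),
                                        key=lambda s: (-len(s), min(s))))]
    return out
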