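"""Readers and writers for PPI edge lists, complex catalogues and solutions.

All formats are flat whitespace/tab-delimited text. Network hygiene
(self-loop removal, duplicate-edge collapsing) is enforced on read: PPI
data here is an undirected simple graph, so ``a b`` and ``b a`` are the
same interaction and ``a a`` is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """An undirected simple graph over opaque string protein IDs.

    Protein IDs are case-sensitive and matched verbatim across files.
    Isolated nodes are permitted.
    """

    species_label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        self.graph.add_edge(a, b)

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph


@dataclass
class ComplexCatalogue:
    """An ordered list of named protein complexes.

    Membership is a set: duplicate members within one record are
    collapsed on read.
    """

    complexes: list[tuple[str, set[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def member_sets(self) -> list[set[str]]:
        return [members for _, members in self.complexes]


def read_ppi_network(path: str | Path, species_label: str) -> PPINetwork:
    """Read a tab/whitespace-delimited edge list into a clean PPINetwork.

    Lines starting with ``#`` are comments; columns beyond the first two
    are ignored. Self-loops and duplicate edges (in either orientation)
    are dropped, with counts logged.

    Raises
    ------
    ValueError
        If a non-comment line has fewer than two tokens.
    """
    net = PPINetwork(species_label=species_label)
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns, got {len(tokens)}")
            a, b = tokens[0], tokens[1]
            if a == b:
                n_self += 1
                continue
            if net.graph.has_edge(a, b):
                n_dup += 1
                continue
            net.graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info("%s (%s): dropped %d self-loops, %d duplicate edges",
                    path, species_label, n_self, n_dup)
    return net


def write_ppi_network(net: PPINetwork, path: str | Path) -> None:
    """Write an edge list (one tab-separated pair per line, sorted)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")
        # isolated nodes are not representable in a pure edge list; note them
        isolated = [n for n in net.graph.nodes if net.graph.degree(n) == 0]
        for n in sorted(isolated):
            fh.write(f"# isolated\t{n}\n")


def read_complexes(path: str | Path, id_column: bool = True) -> ComplexCatalogue:
    """Read a flat complex catalogue, one complex per line.

    With ``id_column=True`` (default) the first token on each line is the
    complex ID; otherwise IDs ``C1, C2, ...`` are assigned by file order.
    Duplicate members within a line are collapsed; records left empty
    after deduplication are dropped with a warning.
    """
    cat = ComplexCatalogue()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s: line %d blank, skipped", path, lineno)
                continue
            tokens = line.split()
            if id_column:
                cid, members = tokens[0], set(tokens[1:])
            else:
                cid, members = f"C{len(cat.complexes) + 1}", set(tokens)
            if not members:
                logger.warning("%s: line %d: complex %s empty after dedup, dropped",
                               path, lineno, cid)
                continue
            cat.complexes.append((cid, members))
    return cat


def write_complexes(cat: ComplexCatalogue, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, members in cat:
            fh.write(cid + "\t" + "\t".join(sorted(members)) + "\n")


_SOLUTION_HEADER = "solution_id\tmembers_net1\tmembers_net2\tlinks"


def write_solutions(solutions: Sequence, path: str | Path) -> None:
    """Write conserved solutions as TSV.

    Columns: solution ID, comma-joined network-one members, comma-joined
    network-two members, comma-joined ``a:b`` homology links.
    """
    with open(path, "w") as fh:
        fh.write(_SOLUTION_HEADER + "\n")
        for i, sol in enumerate(solutions, 1):
            m1 = ",".join(sorted(sol.module_one))
            m2 = ",".join(sorted(sol.module_two))
            links = ",".join(f"{a}:{b}" for a, b in sorted(sol.links))
            fh.write(f"S{i}\t{m1}\t{m2}\t{links}\n")


def read_solutions(path: str | Path) -> list:
    """Read back a solutions TSV written by :func:`write_solutions`."""
    from .align_core import ConservedSolution  # deferred: avoid cycle

    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _SOLUTION_HEADER:
            raise ValueError(f"{path}: unrecognized solutions header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            _, m1, m2, links = line.split("\t")
            link_set = set()
            if links:
                for tok in links.split(","):
                    a, b = tok.split(":")
                    link_set.add((a, b))
            out.append(ConservedSolution(
                module_one=set(m1.split(",")) if m1 else set(),
                module_two=set(m2.split(",")) if m2 else set(),
                links=link_set,
            ))
    return out
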