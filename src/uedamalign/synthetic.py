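"""Paired synthetic PPI networks with planted conserved complexes.

The generator emulates the structure the method assumes: two modular
networks where each planted complex in network one has a mirrored
counterpart in network two, homologous pairs carry strong bidirectional
BLAST E-values, evolution is imitated by edge rewiring on the mirrored
side, missing sequence hits by homolog dropout, and gene duplication by
copying a fraction of network-two module members together with their
edges and homology links (creating many-to-many mappings). Erdős–Rényi
background nodes provide unrelated clutter on both sides.

Everything is deterministic given the seed, so the full pipeline can be
exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align_core import ConservedSolution
from .graph_io import ComplexCatalogue, PPINetwork, write_complexes, write_ppi_network
from .homology import HomologyTable


@dataclass
class SynthParams:
    """Knobs of the planted-complex generator.

    The defaults are the benchmark conditions used throughout the test
    suite: 10 planted complexes of 4-8 proteins, 10% homolog dropout and
    10% edge rewiring on the mirrored side, with a modest Erdős–Rényi
    background. ``evalue_hit`` is the E-value stamped on every true
    homolog pair (both directions) and must clear the 1e-9 seeding
    cutoff.
    """

    n_complexes: int = 10
    complex_size_range: tuple[int, int] = (4, 8)
    intra_edge_prob: float = 0.9
    background_nodes: int = 40
    background_edge_prob: float = 0.01
    homolog_dropout: float = 0.1
    duplicate_rate: float = 0.1
    edge_rewire_rate: float = 0.1
    evalue_hit: float = 1e-50
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid complex_size_range {self.complex_size_range}")
        for name in ("intra_edge_prob", "background_edge_prob", "homolog_dropout",
                     "duplicate_rate", "edge_rewire_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0 < self.evalue_hit < 1e-9):
            raise ValueError("evalue_hit must be positive and below the 1e-9 cutoff")


@dataclass
class GroundTruth:
    """The planted solutions: mirrored module pairs with their links."""

    solutions: list[ConservedSolution] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)


def generate(params: SynthParams) -> tuple[PPINetwork, PPINetwork, HomologyTable,
                                           GroundTruth, ComplexCatalogue]:
    """Generate (netP, netH, homology table, ground truth, catalogue).

    Each planted module is connected by construction (a random spanning
    path) with further edges added at ``intra_edge_prob``; the mirror
    keeps each module edge with probability ``1 - edge_rewire_rate`` and
    replaces rewired edges by random in-module pairs. The homology table
    links mirrored pairs both ways at ``evalue_hit`` minus an exact
    ``homolog_dropout`` fraction chosen at random; ``duplicate_rate`` of
    network-two module members are copied with identical edges and
    links. The catalogue lists the planted network-one modules, ready
    for partitioning.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.complex_size_range
    netP = PPINetwork(species_label="netP")
    netH = PPINetwork(species_label="netH")
    table = HomologyTable()
    truth = GroundTruth()
    cat = ComplexCatalogue()

    all_links: list[tuple[str, str]] = []
    for ci in range(params.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        p_nodes = [f"p{ci}_{k}" for k in range(size)]
        h_nodes = [f"h{ci}_{k}" for k in range(size)]
        mirror = dict(zip(p_nodes, h_nodes))

        # connected module: spanning path over a random order, then extras
        order = [str(x) for x in rng.permutation(p_nodes)]
        edges = {frozenset(e) for e in zip(order, order[1:])}
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < params.intra_edge_prob:
                    edges.add(frozenset((p_nodes[i], p_nodes[j])))
        for e in sorted(tuple(sorted(x)) for x in edges):
            netP.add_edge(*e)

        # mirrored module with rewiring
        for a, b in sorted(tuple(sorted(x)) for x in edges):
            if rng.random() < params.edge_rewire_rate and size > 2:
                x, y = rng.choice(size, size=2, replace=False)
                netH.add_edge(h_nodes[x], h_nodes[y])
            else:
                netH.add_edge(mirror[a], mirror[b])
        for h in h_nodes:           # rewiring may orphan a node; keep it present
            netH.graph.add_node(h)

        links = [(p, mirror[p]) for p in p_nodes]
        all_links.extend(links)
        truth.solutions.append(ConservedSolution(
            module_one=set(p_nodes), module_two=set(h_nodes), links=set(links)))
        cat.complexes.append((f"K{ci}", set(p_nodes)))

    # homolog dropout: delete an exact fraction of planted cross-links
    n_drop = int(round(params.homolog_dropout * len(all_links)))
    dropped = set()
    if n_drop:
        idx = rng.choice(len(all_links), size=n_drop, replace=False)
        dropped = {all_links[i] for i in idx}
    for a, b in all_links:
        if (a, b) not in dropped:
            table.add(a, b, params.evalue_hit, params.evalue_hit)

    # gene duplication on the network-two side: copy node, edges and links
    h_module_nodes = sorted(n for n in netH.nodes if n.startswith("h"))
    n_dup = int(round(params.duplicate_rate * len(h_module_nodes)))
    if n_dup:
        chosen = rng.choice(len(h_module_nodes), size=n_dup, replace=False)
        for i in sorted(chosen):
            h = h_module_nodes[i]
            dup = f"{h}d"
            for nb in sorted(netH.graph.neighbors(h)):
                netH.add_edge(dup, nb)
            for (a, b), (e1, e2) in sorted(table.records.items()):
                if b == h:
                    table.add(a, dup, e1, e2)

    # Erdős–Rényi background on both sides
    for net, prefix in ((netP, "bp"), (netH, "bh")):
        bg = [f"{prefix}{k}" for k in range(params.background_nodes)]
        for n in bg:
            net.graph.add_node(n)
        others = sorted(net.nodes - set(bg))
        for i, u in enumerate(bg):
            for v in bg[i + 1:]:
                if rng.random() < params.background_edge_prob:
                    net.add_edge(u, v)
            for v in others:
                if rng.random() < params.background_edge_prob:
                    net.add_edge(u, v)

    return netP, netH, table, truth, cat


def recovery_fraction(truth: GroundTruth, solutions: list[ConservedSolution],
                      os_threshold: float = 0.2) -> float:
    """Fraction of planted solutions recovered by the predictions.

    A planted solution counts as recovered when some prediction overlaps
    it with OS >= threshold on *both* sides.
    """
    from .evaluation import overlap_score

    if not len(truth):
        raise ValueError("empty ground truth")
    hit = 0
    for t in truth:
        for s in solutions:
            if not s.module_one or not s.module_two:
                continue
            if (overlap_score(s.module_one, t.module_one) >= os_threshold
                    and overlap_score(s.module_two, t.module_two) >= os_threshold):
                hit += 1
                break
    return hit / len(truth)


def write_homology_table(table: HomologyTable, path: str | Path) -> None:
    """Write the 4-column homology TSV the readers expect."""
    with open(path, "w") as fh:
        fh.write("# proteinA\tproteinB\tE_ab\tE_ba\n")
        for (a, b), (e1, e2) in sorted(table.records.items()):
            fh.write(f"{a}\t{b}\t{e1:g}\t{e2:g}\n")


def write_all(params: SynthParams, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the five artifacts into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    netP, netH, table, truth, cat = generate(params)
    paths = {
        "net1": out / "net1.tsv",
        "net2": out / "net2.tsv",
        "homology": out / "homology.tsv",
        "truth": out / "truth.tsv",
        "catalogue": out / "catalogue.txt",
    }
    write_ppi_network(netP, paths["net1"])
    write_ppi_network(netH, paths["net2"])
    write_homology_table(table, paths["homology"])
    from .graph_io import write_solutions
    write_solutions(truth.solutions, paths["truth"])
    write_complexes(cat, paths["catalogue"])
    return paths
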