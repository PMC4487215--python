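"""Conserved-complex detection by dividing and matching.

Each subnetwork of network one seeds a candidate solution: a pair of
modules, ``module_one`` in network one and ``module_two`` in network
two, joined by real homologous mappings (the binary seed matrix A). The
procedure runs in four steps:

1. *Grow.* Admit subnetwork members that are joined by a path of length
   at most ``l`` in network one and share a mapped partner in network
   two (per the walk matrix R, which includes artificial mappings);
   admission also demands support from real mappings — either a direct
   A-link from the pair to the shared partner, or two distinct shared
   partners each really matched elsewhere in the subnetwork. Only
   A-supported partners enter module_two.
2. *Refine.* Reduce many-to-many mappings in module_two: components of
   module_two under depth-``r`` bounded connectivity of size >= 2 cover
   their module_one counterparts; singleton components whose
   counterparts are covered are dropped, and singletons competing for an
   uncovered counterpart keep only the highest walk weight.
3. *Attach.* Subnetwork members left out of module_one re-enter if their
   true homolog is in module_two or reaches it within ``r`` steps; then
   members of either module with no A-link into the other are discarded.
4. *Filter.* A solution is removed when a retained solution with a
   strictly larger network-one complex overlaps it with OS > t
   (OS(B,C) = |B∩C|²/(|B||C|); t = 0.8).

The whole procedure is then repeated with the two networks' roles
reversed (swapping l with r and transposing R and A) before filtering.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

from .birandom_walk import MappingMatrix
from .graph_io import PPINetwork
from .homology import SeedMatrix
from .partition import Subnetwork

logger = logging.getLogger(__name__)


@dataclass
class LenientCriteria:
    """Path-length leniency: ``l`` bounds network one, ``r`` network two."""

    l: int = 2
    r: int = 2

    def __post_init__(self):
        if self.l < 1 or self.r < 1:
            raise ValueError("l and r must be >= 1")

    def swapped(self) -> "LenientCriteria":
        return LenientCriteria(l=self.r, r=self.l)


@dataclass
class ConservedSolution:
    """A conserved complex pair: one protein set per network, linked by A."""

    module_one: set[str]
    module_two: set[str]
    links: set[tuple[str, str]] = field(default_factory=set)
    origin_subnetwork: Subnetwork | None = None

    def swap_sides(self) -> "ConservedSolution":
        return ConservedSolution(
            module_one=set(self.module_two),
            module_two=set(self.module_one),
            links={(b, a) for a, b in self.links},
            origin_subnetwork=self.origin_subnetwork,
        )


def bounded_connected(net: PPINetwork, anchor_set: set[str], candidate: str,
                      depth: int) -> bool:
    """True iff a path of length <= depth joins candidate to any anchor.

    Paths may pass through any node of the network. A candidate absent
    from the network is never connected.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if candidate not in net:
        logger.debug("bounded_connected: %s not in network %s", candidate,
                     net.species_label)
        return False
    if candidate in anchor_set:
        return True
    return len(_bounded_reach(net, candidate, depth) & anchor_set) > 0


def _bounded_reach(net: PPINetwork, source: str, depth: int) -> set[str]:
    """Nodes within graph distance <= depth of source (excluding source)."""
    seen = {source}
    frontier = [source]
    reach: set[str] = set()
    for _ in range(depth):
        nxt = []
        for u in frontier:
            for v in net.graph.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    reach.add(v)
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return reach


def grow_modules(sub: Subnetwork, netP: PPINetwork, netH: PPINetwork,
                 R: MappingMatrix, A: SeedMatrix,
                 crit: LenientCriteria) -> ConservedSolution:
    """Step 1: grow module_one from the subnetwork and seed module_two.

    A pair of subnetwork members joined by a path of length <= l shares
    admission when they map to a common network-two protein under R and
    either (a) that shared partner is really matched (per A) to one of
    the pair, or (b) two distinct shared partners are each really
    matched to subnetwork members outside the pair's neighborhood.
    Growth is connected: starting from the lexicographically smallest
    member with an admissible pair, members are absorbed while they form
    admissible pairs with the module grown so far. Pair admissibility
    depends only on R, A and the subnetwork, so the run is deterministic.
    Only really-matched partners enter module_two.

    A singleton subnetwork degenerates to its node plus its real
    homologs (refined by the later steps).
    """
    members = sorted(sub.members & netP.nodes)
    module_one: set[str] = set()
    module_two: set[str] = set()

    if len(members) == 1:
        u = members[0]
        real = A.homologs_of_one(u) & netH.nodes
        if real:
            return ConservedSolution(module_one={u}, module_two=set(real),
                                     origin_subnetwork=sub)
        return ConservedSolution(module_one=set(), module_two=set(),
                                 origin_subnetwork=sub)

    member_set = set(members)
    # mapped partners per R (known + artificial) and real homologs per A
    partners = {u: set(R.mapped_partners(u)) & netH.nodes for u in members}
    real = {u: A.homologs_of_one(u) & netH.nodes for u in members}
    # real homologs of *any* subnetwork member, with their owners
    owners: dict[str, set[str]] = {}
    for u in members:
        for w in real[u]:
            owners.setdefault(w, set()).add(u)

    nbrs = {u: sorted((_bounded_reach(netP, u, crit.l) & member_set)) for u in members}

    # admissibility of a pair depends only on R, A and the subnetwork
    admissible: dict[tuple[str, str], set[str]] = {}
    for u in members:
        for v in nbrs[u]:
            if (v, u) in admissible:
                continue
            shared = partners[u] & partners[v]
            if not shared:
                continue
            pair_zone = {u, v} | set(nbrs[u])
            supported: set[str] = set()
            # (a) a shared partner really matched to the node or its neighbor
            supported |= shared & (real[u] | real[v])
            # (b) two distinct shared partners matched elsewhere in the sub
            elsewhere = {w for w in shared if owners.get(w, set()) - pair_zone}
            if len(elsewhere) >= 2:
                supported |= elsewhere
            if supported:
                admissible[(u, v)] = supported

    # connected growth: start from the smallest member with an admissible
    # pair and absorb neighbors reachable through admissible pairs
    pair_nbrs: dict[str, set[str]] = {}
    for (u, v) in admissible:
        pair_nbrs.setdefault(u, set()).add(v)
        pair_nbrs.setdefault(v, set()).add(u)
    if pair_nbrs:
        start = min(pair_nbrs)
        module_one = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in sorted(pair_nbrs.get(u, ())):
                if v not in module_one:
                    module_one.add(v)
                    queue.append(v)
        for (u, v), supported in admissible.items():
            if u in module_one and v in module_one:
                # only real homologous proteins enter module_two
                module_two.update(w for w in supported if w in owners)

    return ConservedSolution(module_one=module_one, module_two=module_two,
                             origin_subnetwork=sub)


def _bounded_components(nodes: set[str], net: PPINetwork, depth: int) -> list[set[str]]:
    """Partition nodes into components under depth-bounded connectivity.

    Two nodes are joined when a path of length <= depth connects them in
    the full network (intermediate nodes need not belong to the set).
    """
    nodes = {n for n in nodes if n in net}
    comps: list[set[str]] = []
    left = set(nodes)
    while left:
        start = min(left)
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            hits = _bounded_reach(net, u, depth) & left - comp
            for v in hits:
                comp.add(v)
                queue.append(v)
        comps.append(comp)
        left -= comp
    return comps


def refine_module_two(sol: ConservedSolution, netH: PPINetwork, R: MappingMatrix,
                      crit: LenientCriteria) -> ConservedSolution:
    """Step 2: prune many-to-many mappings from module_two.

    Each module_two node is weighted by its summed walk score to
    module_one. Depth-r components of size >= 2 survive and mark their
    module_one counterparts covered; a singleton survives only if it
    competes for an uncovered counterpart and carries the highest weight
    among its competitors (ties break to the lexicographically smallest
    ID).
    """
    Rt = R.transpose()

    def weight(w: str) -> float:
        return sum(v for x, v in Rt.mapped_partners(w).items()
                   if x in sol.module_one)

    def counterparts(ws: set[str]) -> set[str]:
        out: set[str] = set()
        for w in ws:
            out |= {x for x in Rt.mapped_partners(w) if x in sol.module_one}
        return out

    comps = _bounded_components(sol.module_two, netH, crit.r)
    keep: set[str] = set()
    covered: set[str] = set()
    singles: list[str] = []
    for comp in comps:
        if len(comp) >= 2:
            keep |= comp
            covered |= counterparts(comp)
        else:
            singles.extend(comp)

    # singletons: drop if all their counterparts are covered; otherwise the
    # highest-weight competitor per uncovered counterpart survives
    contenders: dict[str, list[str]] = {}
    for w in singles:
        cps = counterparts({w})
        un = cps - covered
        if not un:
            continue
        for x in un:
            contenders.setdefault(x, []).append(w)
    for x, ws in contenders.items():
        # deterministic tie-break: highest weight, then smallest ID
        best = sorted(ws, key=lambda w: (-weight(w), w))[0]
        keep.add(best)

    # module_two nodes absent from the network cannot join any component
    dropped = sol.module_two - keep
    if dropped:
        logger.debug("refine_module_two: dropped %d of %d", len(dropped),
                     len(sol.module_two))
    return ConservedSolution(module_one=set(sol.module_one), module_two=keep,
                             origin_subnetwork=sol.origin_subnetwork)


def attach_isolated(sol: ConservedSolution, sub: Subnetwork, netH: PPINetwork,
                    A: SeedMatrix, crit: LenientCriteria) -> ConservedSolution:
    """Step 3: re-admit isolated subnetwork members, then enforce linkage.

    A subnetwork member outside module_one joins when its true homolog
    (per A) already sits in module_two, or reaches module_two by a path
    of length <= r in network two (then the homolog joins module_two).
    Finally members of either module without an A-link into the other
    module are discarded, to a fixpoint.
    """
    m1 = set(sol.module_one)
    m2 = set(sol.module_two)
    for u in sorted(sub.members - m1):
        true_homs = A.homologs_of_one(u) & netH.nodes
        if not true_homs:
            continue
        if true_homs & m2:
            m1.add(u)
            continue
        joining = {w for w in true_homs
                   if m2 and bounded_connected(netH, m2, w, crit.r)}
        if joining:
            m1.add(u)
            m2 |= joining

    # keep only members with a real homologous link into the other module
    pairs = A.pairs()
    while True:
        links = {(a, b) for (a, b) in pairs if a in m1 and b in m2}
        keep1 = {a for a, _ in links}
        keep2 = {b for _, b in links}
        if keep1 == m1 and keep2 == m2:
            break
        m1, m2 = keep1, keep2
    return ConservedSolution(module_one=m1, module_two=m2, links=links,
                             origin_subnetwork=sol.origin_subnetwork)


def _run_steps(sub: Subnetwork, netP: PPINetwork, netH: PPINetwork,
               R: MappingMatrix, A: SeedMatrix,
               crit: LenientCriteria) -> ConservedSolution | None:
    sol = grow_modules(sub, netP, netH, R, A, crit)
    if not sol.module_one or not sol.module_two:
        return None
    sol = refine_module_two(sol, netH, R, crit)
    sol = attach_isolated(sol, sub, netH, A, crit)
    if not sol.module_one or not sol.module_two:
        return None
    return sol


def align(netP: PPINetwork, netH: PPINetwork, subsP: list[Subnetwork],
          subsH: list[Subnetwork], R: MappingMatrix, A: SeedMatrix,
          crit: LenientCriteria, overlap_t: float = 0.8) -> list[ConservedSolution]:
    """Full detection: Steps 1-3 per subnetwork, role reversal, Step 4.

    Solutions grown from subnetworks of network two (``subsH``; may be
    empty to skip the reversal) are side-swapped so that ``module_one``
    always holds network-one proteins.
    """
    n1, m1 = len(A.index1), len(A.index2)
    if R.R.shape != (n1, m1):
        raise ValueError(f"R is {R.R.shape}, A is {(n1, m1)}")

    solutions: list[ConservedSolution] = []
    for sub in subsP:
        sol = _run_steps(sub, netP, netH, R, A, crit)
        if sol is not None:
            solutions.append(sol)

    if subsH:
        Rt = R.transpose()
        At = A.transpose()
        crit_t = crit.swapped()
        for sub in subsH:
            sol = _run_steps(sub, netH, netP, Rt, At, crit_t)
            if sol is not None:
                solutions.append(sol.swap_sides())

    logger.info("align: %d candidate solutions before overlap filter",
                len(solutions))
    return filter_overlaps(solutions, t=overlap_t)


def overlap_score_sets(B: set[str], C: set[str]) -> float:
    """|B∩C|² / (|B|·|C|) — defined here for the filter; see evaluation."""
    if not B or not C:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(B & C)
    return inter * inter / (len(B) * len(C))


def filter_overlaps(solutions: list[ConservedSolution],
                    t: float = 0.8) -> list[ConservedSolution]:
    """Step 4: drop solutions dominated by a larger overlapping solution.

    A solution is removed iff some retained solution has a strictly
    larger network-one complex with OS of the two network-one complexes
    strictly above ``t``. Candidates are processed in descending
    |module_one| (ties: descending |module_two|, then smallest member),
    so dominators are settled before their victims.
    """
    if not (0 < t <= 1):
        raise ValueError(f"t must be in (0,1], got {t}")

    def key(sol: ConservedSolution):
        return (-len(sol.module_one), -len(sol.module_two),
                tuple(sorted(sol.module_one)))

    retained: list[ConservedSolution] = []
    for sol in sorted(solutions, key=key):
        dominated = any(
            len(r.module_one) > len(sol.module_one)
            and overlap_score_sets(r.module_one, sol.module_one) > t
            for r in retained
        )
        if not dominated:
            retained.append(sol)
    return retained


def distinct_complexes(solutions: list[ConservedSolution],
                       side: str) -> list[set[str]]:
    """Distinct complexes (size >= 2) on one side of the solutions.

    Duplicate proteins within a complex are already collapsed (sets);
    exact-duplicate complexes and complexes of fewer than two proteins
    are dropped. First-occurrence order is preserved.
    """
    if side not in ("one", "two"):
        raise ValueError("side must be 'one' or 'two'")
    seen: set[frozenset] = set()
    out: list[set[str]] = []
    for sol in solutions:
        c = sol.module_one if side == "one" else sol.module_two
        if len(c) < 2:
            continue
        f = frozenset(c)
        if f in seen:
            continue
        seen.add(f)
        out.append(set(c))
    return out
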