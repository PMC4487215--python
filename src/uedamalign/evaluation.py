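"""Scoring predicted conserved complexes and their biological relevance.

Matching against a known catalogue uses the overlap score
``OS(B,C) = |B∩C|²/(|B||C|)``: a prediction matches a known complex when
OS >= 0.2. From the match counts come precision (matched predictions /
predictions), recall (matched known complexes / known total), their
harmonic mean F, the coverage rate (fraction of known-complex protein
occurrences recovered by each known complex's best-overlapping
prediction) and the perfect-match count PM (identical protein sets).

Functional relevance uses Resnik semantic similarity over the Gene
Ontology biological-process DAG: the information content of a term is
``-ln p(term)`` with ``p`` the descendant-closed annotation frequency in
the corpus; two terms score the IC of their most informative common
ancestor, and two proteins the maximum over their annotation term pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .graph_io import ComplexCatalogue

logger = logging.getLogger(__name__)

_GO_RELATIONS = ("is_a", "part_of")
_ASPECT_TO_NAMESPACE = {"P": "biological_process", "F": "molecular_function",
                        "C": "cellular_component"}


def overlap_score(B: set[str], C: set[str]) -> float:
    """Overlap score |B∩C|² / (|B|·|C|), in [0, 1].

    Equals 1 iff the sets are identical, 0 iff disjoint. Raises on an
    empty set.
    """
    if not B or not C:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(B & C)
    return inter * inter / (len(B) * len(C))


@dataclass
class MatchReport:
    """Counts and rates from matching predictions to a known catalogue."""

    PC: int
    MPC: int
    MKC: int
    PM: int
    precision: float
    recall: float
    f_measure: float
    coverage_rate: float
    known_total: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("PC", "MPC", "MKC", "PM", "precision", "recall", "f_measure",
                 "coverage_rate", "known_total")}


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def match_stats(predicted: Sequence[set[str]], known: ComplexCatalogue,
                os_threshold: float = 0.2,
                known_total: int | None = None) -> MatchReport:
    """Match predicted complexes against known ones at an OS threshold.

    A prediction matches a known complex iff their overlap score is at
    least ``os_threshold``. MPC counts matched predictions, MKC matched
    known complexes (each known complex counts once however many
    predictions hit it), PM predictions identical to some known set.
    ``known_total`` is recall's denominator (default: the catalogue
    size); it is logged so the denominator is always explicit.
    """
    if not (0 < os_threshold <= 1):
        raise ValueError(f"os_threshold must be in (0,1], got {os_threshold}")
    known_sets = known.member_sets()
    if known_total is None:
        known_total = len(known_sets)
    logger.info("match_stats: recall denominator known_total=%d", known_total)

    pc = len(predicted)
    matched_pred = 0
    matched_known: set[int] = set()
    pm = 0
    known_frozen = {frozenset(k) for k in known_sets}
    for p in predicted:
        hit = False
        for i, k in enumerate(known_sets):
            if p and k and overlap_score(p, k) >= os_threshold:
                hit = True
                matched_known.add(i)
        if hit:
            matched_pred += 1
        if frozenset(p) in known_frozen:
            pm += 1

    precision = matched_pred / pc if pc else 0.0
    recall = len(matched_known) / known_total if known_total else 0.0
    cr = coverage_rate(predicted, known) if known_sets else 0.0
    return MatchReport(PC=pc, MPC=matched_pred, MKC=len(matched_known), PM=pm,
                       precision=precision, recall=recall,
                       f_measure=f_measure(precision, recall),
                       coverage_rate=cr, known_total=known_total)


def coverage_rate(predicted: Sequence[set[str]], known: ComplexCatalogue) -> float:
    """Σ_i max_j |KC_i ∩ P_j| / Σ_i |KC_i| over known complexes KC_i."""
    known_sets = known.member_sets()
    if not known_sets:
        raise ValueError("coverage rate needs a nonempty known catalogue")
    covered = 0
    total = 0
    for k in known_sets:
        total += len(k)
        covered += max((len(k & p) for p in predicted), default=0)
    return covered / total


# --- GO semantic similarity -------------------------------------------------

@dataclass
class GoAnnotationSet:
    """A GO DAG restricted to one namespace plus protein annotations.

    ``dag`` holds child -> parent edges (is_a / part_of). Information
    content of a term is ``-ln p``, where p is the fraction of annotated
    proteins in the corpus whose annotation closure (terms plus all
    ancestors) contains the term; the namespace root therefore has
    p = 1 and IC = 0.
    """

    dag: nx.DiGraph
    annotations: dict[str, set[str]]
    namespace: str = "biological_process"
    _ic: dict[str, float] = field(default_factory=dict, repr=False)
    _anc: dict[str, frozenset] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._anc = {}
        for t in self.dag.nodes:
            self._anc[t] = frozenset(nx.descendants(self.dag, t) | {t})
        counts: dict[str, int] = {t: 0 for t in self.dag.nodes}
        n_prot = 0
        for prot, terms in self.annotations.items():
            closure: set[str] = set()
            for t in terms:
                if t in self._anc:
                    closure |= self._anc[t]
            if not closure:
                continue
            n_prot += 1
            for t in closure:
                counts[t] += 1
        self._ic = {}
        for t, c in counts.items():
            if n_prot == 0 or c == 0:
                self._ic[t] = 0.0  # unobserved terms carry no information
            else:
                self._ic[t] = -math.log(c / n_prot)

    @classmethod
    def from_files(cls, obo_path: str | Path, gaf_path: str | Path,
                   namespace: str = "biological_process") -> "GoAnnotationSet":
        """Load an OBO 1.2 ontology and a GAF 2.x annotation file.

        Only is_a/part_of edges in the requested namespace are kept;
        annotations are filtered to the matching GAF aspect column.
        """
        import obonet

        multigraph = obonet.read_obo(obo_path)
        dag = nx.DiGraph()
        for t, data in multigraph.nodes(data=True):
            if data.get("namespace", namespace) == namespace:
                dag.add_node(t)
        for u, v, key in multigraph.edges(keys=True):
            if key in _GO_RELATIONS and u in dag and v in dag:
                dag.add_edge(u, v)

        aspect = {v: k for k, v in _ASPECT_TO_NAMESPACE.items()}[namespace]
        annotations: dict[str, set[str]] = {}
        with open(gaf_path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    continue
                prot, term, asp = cols[1], cols[4], cols[8]
                if asp != aspect or term not in dag:
                    continue
                annotations.setdefault(prot, set()).add(term)
        return cls(dag=dag, annotations=annotations, namespace=namespace)

    def ic(self, term: str) -> float:
        if term not in self._ic:
            raise KeyError(f"term {term} not in ontology")
        return self._ic[term]

    def ancestors(self, term: str) -> frozenset:
        if term not in self._anc:
            raise KeyError(f"term {term} not in ontology")
        return self._anc[term]

    def terms_of(self, protein: str) -> set[str]:
        return {t for t in self.annotations.get(protein, set()) if t in self._anc}


def resnik_term_sim(t1: str, t2: str, ann: GoAnnotationSet) -> float:
    """IC of the most informative common ancestor of two GO terms."""
    common = ann.ancestors(t1) & ann.ancestors(t2)
    if not common:
        return 0.0
    return max(ann.ic(t) for t in common)


def protein_fun_sim(p1: str, p2: str, ann: GoAnnotationSet,
                    ann2: GoAnnotationSet | None = None) -> float:
    """Max Resnik similarity over the proteins' annotation term pairs.

    ``ann2`` supplies the second protein's annotations for cross-species
    pairs (the IC corpus is always ``ann``'s); an unannotated protein
    scores 0 (flagged at debug level).
    """
    terms1 = ann.terms_of(p1)
    terms2 = (ann2 or ann).terms_of(p2)
    if not terms1 or not terms2:
        logger.debug("protein_fun_sim: %s or %s unannotated, scoring 0", p1, p2)
        return 0.0
    return max(resnik_term_sim(a, b, ann) for a in terms1 for b in terms2)


def _mean(vals: list[float]) -> float | None:
    return sum(vals) / len(vals) if vals else None


def relevance_averages(solutions: Sequence, ann1: GoAnnotationSet,
                       ann2: GoAnnotationSet) -> tuple[float, float, float, float]:
    """Functional-similarity averages over conserved solutions.

    Per solution: ``avg_one`` is the mean pairwise similarity within
    module_one, ``avg_two`` within module_two, ``avg_inter`` over
    cross-network pairs only, and ``avg_mixed`` over all pairs (within
    both modules plus across). Returned values are unweighted means over
    solutions; a single-protein module contributes no within-average.
    Cross-species term pairs take their IC from ``ann1``'s corpus, so
    for strict cross-species comparability build one pooled annotation
    set over both species and pass it as both arguments.
    """
    if not solutions:
        raise ValueError("relevance_averages needs at least one solution")
    per_mixed, per_one, per_two, per_inter = [], [], [], []
    for sol in solutions:
        m1 = sorted(sol.module_one)
        m2 = sorted(sol.module_two)
        within1 = [protein_fun_sim(a, b, ann1) for a, b in itertools.combinations(m1, 2)]
        within2 = [protein_fun_sim(a, b, ann2) for a, b in itertools.combinations(m2, 2)]
        inter = [protein_fun_sim(a, b, ann1, ann2) for a in m1 for b in m2]
        v = _mean(within1)
        if v is not None:
            per_one.append(v)
        v = _mean(within2)
        if v is not None:
            per_two.append(v)
        v = _mean(inter)
        if v is not None:
            per_inter.append(v)
        v = _mean(within1 + within2 + inter)
        if v is not None:
            per_mixed.append(v)
    return (_mean(per_mixed) or 0.0, _mean(per_one) or 0.0,
            _mean(per_two) or 0.0, _mean(per_inter) or 0.0)
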