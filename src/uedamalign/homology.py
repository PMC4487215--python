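"""Homology seeding: the binary seed matrix A and walk transition matrices.

Cross-network homology comes in as bidirectional BLAST E-values. A pair
is a "real" homologous mapping when both directional E-values fall below
a cutoff (1e-9 by default); such pairs seed the binary matrix A. The
E-value mean ``(E_ab + E_ba)/2`` is kept only as a diagnostic similarity
-- downstream stages consume A as 0/1.

The transition matrices drive the bi-random walk: P is the row-normalized
adjacency of network one (``p(i,j) = 1/degree(i)`` on edges), H the
column-normalized adjacency of network two (``h(i,j) = 1/degree(j)``).
Isolated nodes yield all-zero rows/columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graph_io import PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class HomologyTable:
    """Cross-network protein pairs with directional E-values.

    At most one record per ordered pair (a, b); a is a network-one
    protein, b network-two.
    """

    records: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def add(self, a: str, b: str, e_ab: float, e_ba: float) -> None:
        if e_ab < 0 or e_ba < 0:
            raise ValueError(f"negative E-value for ({a},{b})")
        self.records[(a, b)] = (e_ab, e_ba)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SeedMatrix:
    """Binary N x M matrix of real homologous mappings.

    ``index1``/``index2`` map protein IDs of networks one/two to row and
    column positions of the sparse matrix ``A``.
    """

    A: sp.csr_matrix
    index1: dict[str, int]
    index2: dict[str, int]

    @property
    def proteins1(self) -> list[str]:
        return list(self.index1)

    @property
    def proteins2(self) -> list[str]:
        return list(self.index2)

    def pairs(self) -> set[tuple[str, str]]:
        """All (protein-one, protein-two) pairs with a(i,j) = 1."""
        rev1 = {v: k for k, v in self.index1.items()}
        rev2 = {v: k for k, v in self.index2.items()}
        coo = self.A.tocoo()
        return {(rev1[i], rev2[j]) for i, j in zip(coo.row, coo.col)}

    def transpose(self) -> "SeedMatrix":
        """Role-swapped seed matrix: network two becomes network one."""
        return SeedMatrix(A=self.A.T.tocsr(), index1=self.index2, index2=self.index1)

    def homologs_of_one(self, protein: str) -> set[str]:
        """Network-two proteins really matched to a network-one protein."""
        i = self.index1.get(protein)
        if i is None:
            return set()
        rev2 = {v: k for k, v in self.index2.items()}
        row = self.A.getrow(i)
        return {rev2[j] for j in row.indices}


@dataclass
class TransitionMatrix:
    """Square stochastic-or-zero matrix over one network's proteins."""

    matrix: sp.csr_matrix
    index: dict[str, int]
    orientation: str  # "row" | "column"


def sequence_similarity(e_ab: float, e_ba: float) -> float:
    """Mean of the two directional BLAST E-values.

    This is the sequence-based similarity attached to a homologous pair;
    it is diagnostic only (the seed matrix is binary).
    """
    if e_ab < 0 or e_ba < 0:
        raise ValueError("E-values must be nonnegative")
    return (e_ab + e_ba) / 2


def read_homology_table(path: str | Path, merge_directional: bool = False) -> HomologyTable:
    """Read a homology table.

    Default format: TSV ``[proteinA, proteinB, E_ab, E_ba]``. With
    ``merge_directional=True``, BLAST-tabular style rows
    ``[query, subject, E]`` are merged: a row (a, b, e) supplies E_ab and
    a row (b, a, e) supplies E_ba; pairs missing either direction keep
    the missing side as +inf (which always fails the cutoff).
    """
    table = HomologyTable()
    if not merge_directional:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tok = line.split()
                if len(tok) < 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 columns")
                table.add(tok[0], tok[1], float(tok[2]), float(tok[3]))
        return table

    fwd: dict[tuple[str, str], float] = {}
    rev: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            a, b, e = tok[0], tok[1], float(tok[2])
            # direction is resolved by pairing rows (a,b) with rows (b,a)
            if (b, a) in fwd and (a, b) not in fwd:
                rev[(b, a)] = min(rev.get((b, a), np.inf), e)
            else:
                fwd[(a, b)] = min(fwd.get((a, b), np.inf), e)
    for (a, b), e_ab in fwd.items():
        table.add(a, b, e_ab, rev.get((a, b), np.inf))
    return table


def build_seed_matrix(table: HomologyTable, net1: PPINetwork, net2: PPINetwork,
                      cutoff: float = 1e-9) -> SeedMatrix:
    """Build the binary seed matrix A over ``net1 x net2``.

    ``a(i,j) = 1`` iff a record (i, j) has both E-values strictly below
    ``cutoff`` and both proteins occur in their networks. Records naming
    unknown proteins are dropped with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    index1 = {p: i for i, p in enumerate(sorted(net1.nodes))}
    index2 = {p: i for i, p in enumerate(sorted(net2.nodes))}
    rows, cols = [], []
    n_dropped = 0
    for (a, b), (e_ab, e_ba) in table.records.items():
        if a not in index1 or b not in index2:
            n_dropped += 1
            continue
        if e_ab < cutoff and e_ba < cutoff:
            rows.append(index1[a])
            cols.append(index2[b])
    if n_dropped:
        logger.warning("build_seed_matrix: dropped %d records naming proteins "
                       "absent from their network", n_dropped)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(index1), len(index2)))
    return SeedMatrix(A=A, index1=index1, index2=index2)


def normalize(net: PPINetwork, orientation: str) -> TransitionMatrix:
    """Degree-normalize a network's adjacency matrix.

    Row orientation: ``p(i,j) = 1/degree(i)`` on edges (each row sums to
    1, or 0 for isolated nodes). Column orientation normalizes by the
    column node's degree instead.
    """
    if orientation not in ("row", "column"):
        raise ValueError(f"orientation must be 'row' or 'column', got {orientation!r}")
    index = {p: i for i, p in enumerate(sorted(net.nodes))}
    n = len(index)
    deg = {p: net.graph.degree(p) for p in index}
    rows, cols, vals = [], [], []
    for a, b in net.graph.edges:
        ia, ib = index[a], index[b]
        # entry (i,j): divide by degree(i) for row orientation, degree(j) for column
        if orientation == "row":
            vals.extend((1.0 / deg[a], 1.0 / deg[b]))
        else:
            vals.extend((1.0 / deg[b], 1.0 / deg[a]))
        rows.extend((ia, ib))
        cols.extend((ib, ia))
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(matrix=M, index=index, orientation=orientation)
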