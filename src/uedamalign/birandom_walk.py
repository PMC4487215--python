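"""Unbalanced bi-random walk over two PPI networks.

Starting from the binary seed matrix A of real homologous mappings, the
walk propagates mapping mass through both networks simultaneously, but
for *unequal* numbers of steps: up to ``l`` steps through network one
(left-multiplication by its row-normalized adjacency P) and up to ``r``
steps through network two (right-multiplication by its column-normalized
adjacency H). The result R scores both the seeded pairs and "artificial"
homologous mappings — cross-network pairs reachable from a seed within
the step bounds but with no direct sequence hit of their own.

The update at step t is the convex combination

    R_t = alpha * (lam_p * P @ R_{t-1} + lam_h * R_{t-1} @ H) / (lam_p + lam_h)
          + (1 - alpha) * A

with indicators ``lam_p = 1 if t <= l`` and ``lam_h = 1 if t <= r``;
iteration runs for exactly ``max(l, r)`` steps (no convergence test —
the walk is deliberately short-range, unlike run-to-convergence global
aligners). A regularizes every step, so seeded pairs never lose their
anchor. With binary A and 0 < alpha < 1 every entry of R stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.sparse as sp

from .homology import SeedMatrix, TransitionMatrix


@dataclass
class WalkParams:
    """Step bounds and seed weight for the bi-random walk.

    l, r : maximum walk steps on network one / network two (>= 0).
    alpha : weight of propagated mass versus the seed matrix, in (0, 1).
    """

    l: int = 2
    r: int = 2
    alpha: float = 0.5

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.l < 0 or self.r < 0:
            raise ValueError("l and r must be nonnegative")


@dataclass
class MappingMatrix:
    """Nonnegative cross-network mapping scores R, indexed like the seed."""

    R: sp.csr_matrix
    index1: dict[str, int]
    index2: dict[str, int]
    params: WalkParams

    def score(self, p1: str, p2: str) -> float:
        i = self.index1.get(p1)
        j = self.index2.get(p2)
        if i is None or j is None:
            return 0.0
        return float(self.R[i, j])

    def mapped_partners(self, p1: str, min_score: float = 0.0) -> dict[str, float]:
        """Network-two proteins with R(p1, .) > min_score (known + artificial)."""
        i = self.index1.get(p1)
        if i is None:
            return {}
        rev2 = {v: k for k, v in self.index2.items()}
        row = self.R.getrow(i)
        return {rev2[j]: float(v) for j, v in zip(row.indices, row.data) if v > min_score}

    def transpose(self) -> "MappingMatrix":
        """Role-swapped view: network two becomes network one."""
        return MappingMatrix(
            R=self.R.T.tocsr(),
            index1=self.index2,
            index2=self.index1,
            params=WalkParams(l=self.params.r, r=self.params.l, alpha=self.params.alpha),
        )


def bi_random_walk(P: TransitionMatrix, H: TransitionMatrix, A: SeedMatrix,
                   params: WalkParams) -> MappingMatrix:
    """Run the unbalanced bi-random walk and return the mapping matrix R.

    Parameters
    ----------
    P : row-normalized transition matrix of network one (N x N).
    H : column-normalized transition matrix of network two (M x M).
    A : binary seed matrix (N x M).
    params : step bounds l, r and seed weight alpha.

    Raises
    ------
    ValueError
        On orientation or dimension mismatch.
    """
    if P.orientation != "row":
        raise ValueError("P must be row-normalized")
    if H.orientation != "column":
        raise ValueError("H must be column-normalized")
    n, m = A.A.shape
    if P.matrix.shape != (n, n):
        raise ValueError(f"P is {P.matrix.shape}, expected ({n},{n})")
    if H.matrix.shape != (m, m):
        raise ValueError(f"H is {H.matrix.shape}, expected ({m},{m})")

    alpha = params.alpha
    A_csr = A.A.tocsr()
    R = A_csr.copy()
    for t in range(1, max(params.l, params.r) + 1):
        lam_p = 1 if t <= params.l else 0
        lam_h = 1 if t <= params.r else 0
        prop = sp.csr_matrix((n, m))
        if lam_p:
            prop = prop + P.matrix @ R
        if lam_h:
            prop = prop + R @ H.matrix
        R = alpha * prop / (lam_p + lam_h) + (1 - alpha) * A_csr
    R.eliminate_zeros()
    return MappingMatrix(R=R.tocsr(), index1=A.index1, index2=A.index2, params=params)
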