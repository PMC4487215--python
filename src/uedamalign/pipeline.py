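"""End-to-end orchestration: networks + homology -> conserved solutions.

Thin wiring over the library modules so the CLI, the examples and the
tests all run the identical pipeline: seed matrix from E-values, the
unbalanced bi-random walk, partitioning of both networks, Steps 1-4.
"""

from __future__ import annotations

import logging

from .align_core import ConservedSolution, LenientCriteria, align
from .birandom_walk import WalkParams, bi_random_walk
from .graph_io import ComplexCatalogue, PPINetwork
from .homology import HomologyTable, build_seed_matrix, normalize
from .partition import mcl_partition, partition_from_catalogue

logger = logging.getLogger(__name__)


def run_alignment(netP: PPINetwork, netH: PPINetwork, table: HomologyTable,
                  catalogueP: ComplexCatalogue | None = None,
                  catalogueH: ComplexCatalogue | None = None,
                  l: int = 2, r: int = 2, alpha: float = 0.5,
                  cutoff: float = 1e-9, overlap_t: float = 0.8,
                  mcl_inflation: float = 2.0,
                  reverse: bool = True) -> list[ConservedSolution]:
    """Run the full detection pipeline and return filtered solutions.

    Network one is partitioned by ``catalogueP`` when given, else by the
    bundled MCL; with ``reverse`` the roles are also swapped (network
    two partitioned by ``catalogueH`` or MCL) before the overlap filter.
    """
    A = build_seed_matrix(table, netP, netH, cutoff=cutoff)
    P = normalize(netP, "row")
    H = normalize(netH, "column")
    R = bi_random_walk(P, H, A, WalkParams(l=l, r=r, alpha=alpha))

    if catalogueP is not None:
        subsP = partition_from_catalogue(catalogueP, netP)
    else:
        subsP = mcl_partition(netP, inflation=mcl_inflation)
    if reverse:
        if catalogueH is not None:
            subsH = partition_from_catalogue(catalogueH, netH)
        else:
            subsH = mcl_partition(netH, inflation=mcl_inflation)
    else:
        subsH = []

    logger.info("run_alignment: %d + %d subnetworks, %d seed pairs",
                len(subsP), len(subsH), int(A.A.nnz))
    return align(netP, netH, subsP, subsH, R, A,
                 LenientCriteria(l=l, r=r), overlap_t=overlap_t)
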