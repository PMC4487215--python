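"""The unbalanced bi-random walk on a minimal two-edge instance.

Networks are single edges u1-u2 and v1-v2 with one sequence-based
(real) mapping u1-v1. One walk step on each side (l = r = 1,
alpha = 0.5) spreads half of the retained seed mass to the neighbors:
the positive scores at (u2, v1) and (u1, v2) are *artificial*
homologous mappings — no sequence hit of their own, inferred purely
from the networks.
"""

from uedamalign import (HomologyTable, PPINetwork, WalkParams, bi_random_walk,
                        build_seed_matrix, normalize)

netP = PPINetwork("one")
netP.add_edge("u1", "u2")
netH = PPINetwork("two")
netH.add_edge("v1", "v2")

table = HomologyTable()
table.add("u1", "v1", 1e-50, 1e-50)   # strong hit, both BLAST directions

A = build_seed_matrix(table, netP, netH)          # binary seeds below 1e-9
P = normalize(netP, "row")
H = normalize(netH, "column")
R = bi_random_walk(P, H, A, WalkParams(l=1, r=1, alpha=0.5))

for u in ("u1", "u2"):
    for v in ("v1", "v2"):
        kind = "real" if (u, v) in A.pairs() else (
            "artificial" if R.score(u, v) > 0 else "none")
        print(f"R({u},{v}) = {R.score(u, v):.2f}  [{kind}]")
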