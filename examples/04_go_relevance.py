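"""Functional relevance of a conserved solution via Resnik similarity.

A toy biological-process DAG (root <- A, B; A <- C; A, B <- D) with
three annotated proteins gives hand-checkable information contents:
p(A) = 2/3 so IC(A) = ln 1.5, and the most informative common ancestor
of C and D is A. Protein similarity is the max Resnik score over their
annotation term pairs; the solution-level averages separate
within-module and cross-network pairs.
"""

import math

import networkx as nx

from uedamalign import ConservedSolution, GoAnnotationSet, protein_fun_sim, relevance_averages

dag = nx.DiGraph()
dag.add_edges_from([("A", "root"), ("B", "root"), ("C", "A"),
                    ("D", "A"), ("D", "B")])
ann = GoAnnotationSet(dag=dag,
                      annotations={"p1": {"C"}, "p2": {"D"}, "p3": {"B"}})

print(f"IC(A) = {ann.ic('A'):.4f} (expect ln 1.5 = {math.log(1.5):.4f})")
print(f"sim(p1, p2) = {protein_fun_sim('p1', 'p2', ann):.4f} "
      "(most informative common ancestor of C and D is A)")

sol = ConservedSolution(module_one={"p1", "p2"}, module_two={"p2", "p3"})
mixed, one, two, inter = relevance_averages([sol], ann, ann)
print(f"avg_mixed = {mixed:.4f}  avg_one = {one:.4f}  "
      f"avg_two = {two:.4f}  avg_inter = {inter:.4f}")
# avg_one/avg_two average within each module; avg_inter only
# cross-network pairs; avg_mixed pools all pairs
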