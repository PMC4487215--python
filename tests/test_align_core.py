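"""The four detection steps: growth, refinement, attachment, filtering."""

import itertools

import networkx as nx
import numpy as np
import pytest

from uedamalign import (ConservedSolution, HomologyTable, LenientCriteria,
                        WalkParams, align, attach_isolated, bi_random_walk,
                        bounded_connected, build_seed_matrix, distinct_complexes,
                        filter_overlaps, grow_modules, normalize,
                        refine_module_two)
from uedamalign.partition import Subnetwork

from conftest import mapping_from_scores, net_from_edges, seed_from_pairs


def pipeline_matrices(netP, netH, pairs, l=2, r=2):
    table = HomologyTable()
    for a, b in pairs:
        table.add(a, b, 1e-30, 1e-30)
    A = build_seed_matrix(table, netP, netH)
    R = bi_random_walk(normalize(netP, "row"), normalize(netH, "column"), A,
                       WalkParams(l=l, r=r))
    return R, A


class TestBoundedConnected:
    def test_adjacent_anchor(self):
        net = net_from_edges([("a", "b")])
        assert bounded_connected(net, {"a"}, "b", 2)

    def test_beyond_depth(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        assert not bounded_connected(net, {"a"}, "d", 2)
        assert bounded_connected(net, {"a"}, "d", 3)

    def test_candidate_absent(self):
        net = net_from_edges([("a", "b")])
        assert not bounded_connected(net, {"a"}, "zzz", 2)

    def test_agrees_with_shortest_path_oracle(self):
        """50 random 12-node graphs, depths 1-4, versus networkx APSP."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = nx.gnp_random_graph(12, 0.2, seed=int(rng.integers(2**31)))
            net = net_from_edges([(f"n{a}", f"n{b}") for a, b in g.edges],
                                 extra_nodes=[f"n{i}" for i in range(12)])
            dist = dict(nx.all_pairs_shortest_path_length(net.graph))
            nodes = sorted(net.nodes)
            for _ in range(5):
                anchors = set(rng.choice(nodes, size=3, replace=False))
                for cand in nodes:
                    for depth in range(1, 5):
                        oracle = any(dist[cand].get(a, 99) <= depth
                                     for a in anchors)
                        assert bounded_connected(net, anchors, cand, depth) == oracle


class TestGrowModules:
    def test_mirrored_pair(self):
        netP = net_from_edges([("u1", "u2")], "P")
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1"), ("u2", "v2")])
        sub = Subnetwork("P", {"u1", "u2"}, "known_complex")
        sol = grow_modules(sub, netP, netH, R, A, LenientCriteria(2, 2))
        assert sol.module_one == {"u1", "u2"}
        assert sol.module_two == {"v1", "v2"}

    def test_node_without_mapping_excluded(self):
        # u3 sits 3 hops from the seeded pair: the l=2 walk leaves its R
        # row empty, so it shares no mapped partner and stays out
        netP = net_from_edges([("u1", "u2"), ("u2", "x1"), ("x1", "x2"),
                               ("x2", "u3")], "P")
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1"), ("u2", "v2")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        sol = grow_modules(sub, netP, netH, R, A, LenientCriteria(2, 2))
        assert "u3" not in sol.module_one

    def test_artificially_shared_partner_admits_neighbor(self):
        # u3 has no sequence hit of its own, but the walk maps it to v2,
        # which is really matched to its neighbor u2: condition (a) admits it
        netP = net_from_edges([("u1", "u2"), ("u2", "u3")], "P")
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1"), ("u2", "v2")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        sol = grow_modules(sub, netP, netH, R, A, LenientCriteria(2, 2))
        assert sol.module_one == {"u1", "u2", "u3"}
        assert sol.module_two == {"v1", "v2"}

    def test_singleton_subnetwork_degenerates(self):
        netP = net_from_edges([], "P", extra_nodes=["u1"])
        netH = net_from_edges([], "H", extra_nodes=["v1"])
        R, A = pipeline_matrices(netP, netH, [("u1", "v1")])
        sub = Subnetwork("P", {"u1"}, "known_complex")
        sol = grow_modules(sub, netP, netH, R, A, LenientCriteria(2, 2))
        assert sol.module_one == {"u1"} and sol.module_two == {"v1"}


class TestRefineModuleTwo:
    def test_connected_pair_unchanged(self):
        netH = net_from_edges([("v1", "v2")], "H")
        R = mapping_from_scores({("u1", "v1"): 0.5, ("u2", "v2"): 0.5},
                                ["u1", "u2"], ["v1", "v2"])
        sol = ConservedSolution(module_one={"u1", "u2"}, module_two={"v1", "v2"})
        out = refine_module_two(sol, netH, R, LenientCriteria(2, 2))
        assert out.module_two == {"v1", "v2"}

    def test_covered_singletons_both_removed(self):
        # v1-v2 form a component covering u1, u2; w1 and w2 are isolated
        # singletons mapping only to the covered u1 -> both dropped
        netH = net_from_edges([("v1", "v2")], "H", extra_nodes=["w1", "w2"])
        R = mapping_from_scores(
            {("u1", "v1"): 0.5, ("u2", "v2"): 0.5,
             ("u1", "w1"): 0.4, ("u1", "w2"): 0.3},
            ["u1", "u2"], ["v1", "v2", "w1", "w2"])
        sol = ConservedSolution(module_one={"u1", "u2"},
                                module_two={"v1", "v2", "w1", "w2"})
        out = refine_module_two(sol, netH, R, LenientCriteria(2, 2))
        assert out.module_two == {"v1", "v2"}

    def test_uncovered_singletons_keep_highest_weight(self):
        netH = net_from_edges([], "H", extra_nodes=["w1", "w2"])
        R = mapping_from_scores({("u1", "w1"): 0.7, ("u1", "w2"): 0.3},
                                ["u1"], ["w1", "w2"])
        sol = ConservedSolution(module_one={"u1"}, module_two={"w1", "w2"})
        out = refine_module_two(sol, netH, R, LenientCriteria(2, 2))
        assert out.module_two == {"w1"}

    def test_equal_weight_tie_breaks_lexicographically(self):
        netH = net_from_edges([], "H", extra_nodes=["w1", "w2"])
        R = mapping_from_scores({("u1", "w1"): 0.5, ("u1", "w2"): 0.5},
                                ["u1"], ["w1", "w2"])
        sol = ConservedSolution(module_one={"u1"}, module_two={"w1", "w2"})
        out = refine_module_two(sol, netH, R, LenientCriteria(2, 2))
        assert out.module_two == {"w1"}


class TestAttachIsolated:
    def test_isolated_node_with_adjacent_homolog_attached(self):
        # u3 is isolated in netP; its true homolog v3 is adjacent to module_two
        netP = net_from_edges([("u1", "u2")], "P", extra_nodes=["u3"])
        netH = net_from_edges([("v1", "v2"), ("v2", "v3")], "H")
        R, A = pipeline_matrices(netP, netH,
                                 [("u1", "v1"), ("u2", "v2"), ("u3", "v3")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        crit = LenientCriteria(2, 2)
        sol = grow_modules(sub, netP, netH, R, A, crit)
        assert "u3" not in sol.module_one
        sol = refine_module_two(sol, netH, R, crit)
        sol = attach_isolated(sol, sub, netH, A, crit)
        assert sol.module_one == {"u1", "u2", "u3"}
        assert sol.module_two == {"v1", "v2", "v3"}
        assert ("u3", "v3") in sol.links

    def test_isolated_node_without_link_not_attached(self):
        netP = net_from_edges([("u1", "u2")], "P", extra_nodes=["u3"])
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1"), ("u2", "v2")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        crit = LenientCriteria(2, 2)
        sol = attach_isolated(
            refine_module_two(grow_modules(sub, netP, netH, R, A, crit),
                              netH, R, crit), sub, netH, A, crit)
        assert "u3" not in sol.module_one

    def test_homolog_beyond_r_not_attached(self):
        netP = net_from_edges([("u1", "u2")], "P", extra_nodes=["u3"])
        # v3 is 3 hops from the nearest module_two node; r = 2
        netH = net_from_edges([("v1", "v2"), ("v2", "x1"), ("x1", "x2"),
                               ("x2", "v3")], "H")
        R, A = pipeline_matrices(netP, netH,
                                 [("u1", "v1"), ("u2", "v2"), ("u3", "v3")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        crit = LenientCriteria(2, 2)
        sol = attach_isolated(
            refine_module_two(grow_modules(sub, netP, netH, R, A, crit),
                              netH, R, crit), sub, netH, A, crit)
        assert "u3" not in sol.module_one and "v3" not in sol.module_two


def make_sol(m1, m2=None):
    m2 = m2 or {f"x{i}" for i in range(len(m1))}
    return ConservedSolution(module_one=set(m1), module_two=set(m2))


class TestFilterOverlaps:
    def test_equal_sizes_both_kept(self):
        a = make_sol({"a", "b", "c"})
        b = make_sol({"a", "b", "c"})
        assert len(filter_overlaps([a, b])) == 2

    def test_os_below_threshold_both_kept(self):
        a = make_sol({"a", "b", "c", "d"})
        b = make_sol({"a", "b", "c"})
        # OS = 9/12 = 0.75 <= 0.8
        assert len(filter_overlaps([a, b])) == 2

    def test_boundary_os_exactly_t_keeps_both(self):
        a = make_sol({"a", "b", "c", "d", "e"})
        b = make_sol({"a", "b", "c", "d"})
        # OS = 16/20 = 0.8, not strictly larger than t
        assert len(filter_overlaps([a, b], t=0.8)) == 2

    def test_dominated_solution_removed(self):
        a = make_sol({"a", "b", "c", "d", "e"})
        b = make_sol({"a", "b", "c", "d"})
        # OS = 16/20 = 0.8 > t = 0.75 and |a| > |b|
        kept = filter_overlaps([a, b], t=0.75)
        assert len(kept) == 1 and kept[0].module_one == a.module_one

    def test_domain_error(self):
        with pytest.raises(ValueError):
            filter_overlaps([], t=0.0)

    def test_no_retained_pair_violates_rule_on_random_sets(self):
        """Post-filter re-scan over 200 random solution sets."""
        from uedamalign.align_core import overlap_score_sets

        rng = np.random.default_rng(5)
        pool = [f"p{i}" for i in range(12)]
        for _ in range(200):
            sols = [make_sol(set(rng.choice(pool,
                                            size=int(rng.integers(1, 8)),
                                            replace=False)))
                    for _ in range(int(rng.integers(2, 12)))]
            kept = filter_overlaps(sols, t=0.8)
            for s, other in itertools.permutations(kept, 2):
                violates = (len(other.module_one) > len(s.module_one)
                            and overlap_score_sets(other.module_one,
                                                   s.module_one) > 0.8)
                assert not violates


class TestDistinctComplexes:
    def test_dedup_and_min_size(self):
        sols = [make_sol({"a", "b"}), make_sol({"a", "b"}), make_sol({"c"})]
        assert distinct_complexes(sols, "one") == [{"a", "b"}]

    def test_empty(self):
        assert distinct_complexes([], "one") == []

    def test_counts_unique(self):
        sols = [make_sol({"a", "b"}), make_sol({"a", "b"}), make_sol({"c", "d"}),
                make_sol({"e", "f", "g"}), make_sol({"c", "d"})]
        assert len(distinct_complexes(sols, "one")) == 3


class TestAlign:
    def test_empty_inputs(self):
        netP = net_from_edges([("u1", "u2")], "P")
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1")])
        assert align(netP, netH, [], [], R, A, LenientCriteria(2, 2)) == []

    def test_single_mirrored_instance_yields_one_solution(self):
        netP = net_from_edges([("u1", "u2")], "P")
        netH = net_from_edges([("v1", "v2")], "H")
        R, A = pipeline_matrices(netP, netH, [("u1", "v1"), ("u2", "v2")])
        subs = [Subnetwork("P", {"u1", "u2"}, "known_complex")]
        sols = align(netP, netH, subs, [], R, A, LenientCriteria(2, 2))
        assert len(sols) == 1
        assert sols[0].module_one == {"u1", "u2"}
        assert sols[0].module_two == {"v1", "v2"}

    def test_symmetric_instance_side_swap(self):
        """With l = r on a mirrored instance, swapping the networks (and
        transposing R and A) produces the same solutions up to side swap."""
        netP = net_from_edges([("u1", "u2"), ("u2", "u3")], "P")
        netH = net_from_edges([("v1", "v2"), ("v2", "v3")], "H")
        pairs = [("u1", "v1"), ("u2", "v2"), ("u3", "v3")]
        R, A = pipeline_matrices(netP, netH, pairs)
        crit = LenientCriteria(2, 2)
        subsP = [Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")]
        subsH = [Subnetwork("H", {"v1", "v2", "v3"}, "known_complex")]
        fwd = align(netP, netH, subsP, [], R, A, crit)
        rev = align(netH, netP, subsH, [], R.transpose(), A.transpose(), crit)
        fwd_sets = {(frozenset(s.module_one), frozenset(s.module_two)) for s in fwd}
        rev_sets = {(frozenset(s.module_two), frozenset(s.module_one)) for s in rev}
        assert fwd_sets == rev_sets

    def test_step3_attachment_monotone_in_r(self):
        """Enlarging r never loses attachable members on a fixed solution."""
        netP = net_from_edges([("u1", "u2")], "P", extra_nodes=["u3"])
        netH = net_from_edges([("v1", "v2"), ("v2", "x1"), ("x1", "v3")], "H")
        R, A = pipeline_matrices(netP, netH,
                                 [("u1", "v1"), ("u2", "v2"), ("u3", "v3")])
        sub = Subnetwork("P", {"u1", "u2", "u3"}, "known_complex")
        base = ConservedSolution(module_one={"u1", "u2"}, module_two={"v1", "v2"})
        sizes = []
        for r in (1, 2, 3):
            sol = attach_isolated(
                ConservedSolution(module_one=set(base.module_one),
                                  module_two=set(base.module_two)),
                sub, netH, A, LenientCriteria(2, r))
            sizes.append(len(sol.module_one))
        assert sizes == sorted(sizes)

    def test_emitted_solutions_form_connected_units(self):
        """Each emitted solution is one connected unit through depth-l
        edges in network one, depth-r edges in network two, and its
        homology links; every member carries at least one link."""
        from uedamalign import SynthParams, generate
        from uedamalign.pipeline import run_alignment

        netP, netH, table, truth, cat = generate(SynthParams(seed=9))
        sols = run_alignment(netP, netH, table, catalogueP=cat, reverse=False)
        assert sols
        for sol in sols:
            linked1 = {a for a, _ in sol.links}
            linked2 = {b for _, b in sol.links}
            assert sol.module_one == linked1 and sol.module_two == linked2
            g = nx.Graph()
            g.add_nodes_from(("one", n) for n in sol.module_one)
            g.add_nodes_from(("two", n) for n in sol.module_two)
            g.add_edges_from((("one", a), ("two", b)) for a, b in sol.links)
            for members, net, depth, side in ((sol.module_one, netP, 2, "one"),
                                              (sol.module_two, netH, 2, "two")):
                for a in members:
                    reach = nx.single_source_shortest_path_length(
                        net.graph, a, cutoff=depth)
                    for b in members:
                        if b != a and b in reach:
                            g.add_edge((side, a), (side, b))
            assert nx.is_connected(g)
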