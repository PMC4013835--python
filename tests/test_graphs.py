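"""Display graph, ELIG, cuts, separators, and their correspondences."""

import itertools
import random

import networkx as nx
import pytest

from supercut.errors import DomainError, ResourceExhaustedError
from supercut.graphs import (
    Cut,
    _brute_force_minimal_separators,
    build_display_graph,
    build_elig,
    classify_cut,
    cut_to_split,
    cuts_parallel,
    enumerate_minimal_cuts,
    enumerate_minimal_separators,
    full_components,
    is_minimal_cut,
    is_minimal_separator,
    separator_is_legal,
    separators_parallel,
)
from supercut.phylo import Profile, Split, edge_key, parse_newick
from supercut.synthdata import fig1_example_cuts

from conftest import small_random_profiles

E = edge_key


class TestDisplayGraph:
    def test_two_identical_quartets(self):
        p = Profile([parse_newick("((a,b),(c,d));", 0),
                     parse_newick("((a,b),(c,d));", 1)])
        d = build_display_graph(p)
        assert len(d.leaves) == 4
        assert d.graph.number_of_nodes() == 8
        assert d.graph.number_of_edges() == 10

    def test_fig1_contains_the_example_cut_edges(self, fig1):
        d = build_display_graph(fig1)
        for u, v in [("1", "2"), ("2", "3"), ("4", "5"), ("5", "6"),
                     ("6", "7"), ("1", "c"), ("2", "f")]:
            assert d.graph.has_edge(u, v)

    def test_disjoint_labels_disconnect(self):
        p = Profile([parse_newick("((a,b),(c,d));", 0),
                     parse_newick("((w,x),(y,z));", 1)])
        d = build_display_graph(p)
        assert not d.is_connected()
        assert len(d.components()) == 2

    def test_edge_provenance(self, fig1):
        d = build_display_graph(fig1)
        assert d.provenance[E("1", "2")] == frozenset({0})
        assert d.provenance[E("5", "6")] == frozenset({1})
        assert d.tree_slice([E("1", "2"), E("5", "6")], 0) == {E("1", "2")}


class TestELIG:
    def test_line_graph_of_star_is_clique(self):
        p = Profile([parse_newick("(a,b,c);", 0)])
        elig = build_elig(build_display_graph(p))
        assert elig.graph.number_of_nodes() == 3
        assert elig.graph.number_of_edges() == 3  # triangle

    def test_vertex_count_equals_display_edge_count(self):
        for p, _ in small_random_profiles(8):
            d = build_display_graph(p)
            elig = build_elig(d)
            assert elig.graph.number_of_nodes() == d.graph.number_of_edges()

    def test_path_correspondence_under_edge_removal(self):
        # a u-v walk survives in the display graph minus F iff the
        # corresponding walk survives in the ELIG minus F
        rng = random.Random(2)
        for p, _ in small_random_profiles(6):
            d = build_display_graph(p)
            if not d.is_connected():
                continue
            elig = build_elig(d)
            edges = d.edges()
            for _ in range(8):
                f = frozenset(rng.sample(edges, min(3, len(edges))))
                g_cut = nx.restricted_view(d.graph, [], f)
                l_cut = elig.graph.subgraph([e for e in elig.graph if e not in f])
                remaining = [e for e in edges if e not in f]
                for e1, e2 in itertools.combinations(remaining, 2):
                    in_lg = nx.has_path(l_cut, e1, e2)
                    in_g = any(
                        nx.has_path(g_cut, a, b) for a in e1 for b in e2
                    )
                    assert in_lg == in_g


class TestMinimalCuts:
    def test_example_cut_is_minimal(self, fig1):
        d = build_display_graph(fig1)
        assert is_minimal_cut(d.graph, [E("1", "2"), E("5", "6")])

    def test_bridge_and_padded_bridge(self):
        g = nx.path_graph(4)
        assert is_minimal_cut(g, [(1, 2)])
        assert not is_minimal_cut(g, [(0, 1), (2, 3)])  # three components
        g.add_edge(0, 2)
        # bridge (2,3) plus a non-separating edge is not minimal
        assert is_minimal_cut(g, [(2, 3)])
        assert not is_minimal_cut(g, [(2, 3), (0, 1)])

    def test_criteria_equivalence_brute_force(self):
        # the two-components+spanning test agrees with the literal
        # no-proper-subset-disconnects definition on all small edge subsets
        rng = random.Random(1)
        for i in range(12):
            g = nx.gnp_random_graph(7, 0.45, seed=i)
            if not nx.is_connected(g):
                continue
            edges = [edge_key(u, v) for u, v in g.edges()]
            for r in (1, 2, 3):
                for f in itertools.combinations(edges, r):
                    fset = frozenset(f)
                    h = nx.restricted_view(g, [], fset)
                    literal = not nx.is_connected(h) and all(
                        nx.is_connected(nx.restricted_view(g, [], fset - {e}))
                        for e in fset
                    )
                    assert is_minimal_cut(g, fset) == literal

    def test_enumeration_on_small_graphs(self):
        tri = nx.cycle_graph(3)
        cuts = enumerate_minimal_cuts(tri)
        assert sorted(len(c) for c in cuts) == [2, 2, 2]
        path = nx.path_graph(3)
        assert sorted(len(c) for c in enumerate_minimal_cuts(path)) == [1, 1]

    def test_enumeration_contains_the_example_cuts(self, fig1):
        d = build_display_graph(fig1)
        enumerated = {c.edges for c in enumerate_minimal_cuts(d.graph)}
        for c in fig1_example_cuts():
            assert c.edges in enumerated

    def test_guard(self):
        g = nx.path_graph(20)
        with pytest.raises(ResourceExhaustedError):
            enumerate_minimal_cuts(g, max_vertices=18)
        assert enumerate_minimal_cuts(g, max_vertices=25)


class TestClassifyCut:
    def test_example_cut_f3_legal_and_nice(self, fig1):
        d = build_display_graph(fig1)
        f3 = [E("4", "5"), E("1", "2"), E("1", "c")]
        assert classify_cut(d, f3) == (True, True)

    def test_two_nonincident_edges_of_one_tree_illegal(self, fig1):
        d = build_display_graph(fig1)
        assert classify_cut(d, [E("1", "2"), E("3", "d")]) == (False, False)

    def test_isolating_a_leaf_is_not_nice(self, fig1):
        d = build_display_graph(fig1)
        # all edges at leaf g: single leaf edge {7,g} isolates vertex g
        legal, nice = classify_cut(d, [E("7", "g")])
        assert legal and not nice


class TestParallelism:
    def test_example_cuts_pairwise_parallel(self, fig1):
        d = build_display_graph(fig1)
        cuts = list(fig1_example_cuts())
        for c1, c2 in itertools.combinations(cuts, 2):
            assert cuts_parallel(d.graph, c1, c2)

    def test_self_parallel(self, fig1):
        d = build_display_graph(fig1)
        c = fig1_example_cuts()[0]
        assert cuts_parallel(d.graph, c, c)

    def test_crossing_cuts_of_a_cycle(self):
        g = nx.cycle_graph(4)
        f1 = [(0, 1), (2, 3)]
        f2 = [(1, 2), (3, 0)]
        assert not cuts_parallel(g, f1, f2)

    def test_non_minimal_rejected(self, fig1):
        d = build_display_graph(fig1)
        with pytest.raises(DomainError):
            cuts_parallel(d.graph, Cut([E("1", "a")]), fig1_example_cuts()[0])


class TestSeparators:
    def test_example_cut_is_legal_minimal_separator(self, fig1):
        elig = build_elig(build_display_graph(fig1))
        f1 = {E("1", "2"), E("5", "6")}
        assert is_minimal_separator(elig.graph, f1)
        assert separator_is_legal(elig, f1)
        f2 = {E("2", "3"), E("6", "7"), E("5", "6")}
        assert separator_is_legal(elig, f2)

    def test_disjoint_tree_edges_make_illegal_separator(self, fig1):
        elig = build_elig(build_display_graph(fig1))
        assert not separator_is_legal(elig, {E("1", "a"), E("3", "d")})

    def test_neighborhood_separator(self):
        g = nx.path_graph(5)
        assert is_minimal_separator(g, {2})
        comps, nfull = full_components(g, {2})
        assert len(comps) == 2 and nfull == 2

    def test_brute_force_agreement_on_random_graphs(self):
        for i in range(25):
            g = nx.gnp_random_graph(8, 0.4, seed=i)
            if not nx.is_connected(g):
                continue
            fast = enumerate_minimal_separators(g)
            slow = _brute_force_minimal_separators(g)
            assert fast == slow

    def test_no_separator_swallows_a_vertex_neighborhood(self):
        for p, _ in small_random_profiles(6):
            d = build_display_graph(p)
            if not d.is_connected():
                continue
            elig = build_elig(d)
            incs = [
                frozenset(
                    edge_key(v, w) for w in d.graph.neighbors(v)
                )
                for v in d.graph
            ]
            for s in enumerate_minimal_separators(elig.graph):
                assert not any(inc <= s for inc in incs)

    def test_separator_parallelism_definition(self):
        g = nx.cycle_graph(6)
        assert not separators_parallel(g, {0, 3}, {1, 4})
        assert separators_parallel(g, {0, 3}, {0, 3})


class TestCutToSplit:
    def test_example_splits(self, fig1):
        d = build_display_graph(fig1)
        f1, f2, f3, f4 = fig1_example_cuts()
        assert cut_to_split(d, f1) == Split("abc", "defg")
        assert cut_to_split(d, f2) == Split("abcfg", "de")
        assert cut_to_split(d, f3) == Split("ab", "cdefg")
        assert cut_to_split(d, f4) == Split("abcde", "fg")

    def test_not_nice_rejected(self, fig1):
        d = build_display_graph(fig1)
        with pytest.raises(DomainError):
            cut_to_split(d, [E("7", "g")])  # isolates a leaf: not nice

    def test_parallel_nice_cuts_give_compatible_splits(self):
        from supercut.phylo import splits_compatible

        for p, _ in small_random_profiles(10):
            d = build_display_graph(p)
            if not d.is_connected():
                continue
            nice = [
                c
                for c in enumerate_minimal_cuts(d.graph)
                if classify_cut(d, c) == (True, True)
            ]
            for c1, c2 in itertools.combinations(nice, 2):
                if cuts_parallel(d.graph, c1, c2):
                    assert splits_compatible(
                        cut_to_split(d, c1), cut_to_split(d, c2)
                    )

    def test_sole_edge_separates_the_two_subtrees(self):
        for p, _ in small_random_profiles(8):
            d = build_display_graph(p)
            if not d.is_connected():
                continue
            for c in enumerate_minimal_cuts(d.graph):
                for i, t in enumerate(p.trees):
                    sl = d.tree_slice(c.edges, i)
                    if len(sl) != 1:
                        continue
                    (e,) = sl
                    h = nx.restricted_view(d.graph, [], c.edges)
                    comp_u = nx.node_connected_component(h, e[0])
                    assert e[1] not in comp_u
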