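"""Agreement decider, the cut function Psi, and edge splitting."""

import pytest

from supercut.agreement import (
    brute_force_ast,
    cut_function,
    decide_agreement,
    find_agreement_cutset,
    normalize_ast,
    split_edge_at,
)
from supercut.compat import decide_compatibility
from supercut.errors import DomainError
from supercut.graphs import build_display_graph, _components_after
from supercut.phylo import (
    Profile,
    displays_and_agrees,
    edge_key,
    parse_newick,
    restrict_tree,
)
from supercut.synthdata import (
    ProfileRecipe,
    fig2_example_cuts,
    incompatible_fixture,
    random_profile,
)

from conftest import small_random_profiles

E = edge_key


class TestAgreementCutset:
    def test_fig2_has_one_and_printed_cuts_are_a_witness(self, fig2):
        cutset = find_agreement_cutset(fig2)
        assert cutset is not None
        d = build_display_graph(fig2)
        for c in cutset:
            for i in range(len(fig2.trees)):
                assert len(d.tree_slice(c.edges, i)) <= 1
        from supercut.verify import verify_cutset_certificate

        printed = [c.edges for c in fig2_example_cuts()]
        assert verify_cutset_certificate(fig2, printed, agreement=True) == []

    def test_fig1_has_none(self, fig1):
        assert find_agreement_cutset(fig1) is None

    def test_restrictions_of_one_tree_always_agree(self):
        # profiles built by pure restriction (no contraction) have the
        # source tree as an agreement supertree
        for seed in range(6):
            p, truth = random_profile(
                ProfileRecipe(
                    n_labels=6, n_trees=2, subset_size=5,
                    contraction_prob=0.0, seed=seed,
                )
            )
            if not build_display_graph(p).is_connected():
                continue
            assert find_agreement_cutset(p) is not None


class TestDecider:
    def test_fig2_yes_with_agreeing_ast(self, fig2):
        d = decide_agreement(fig2)
        assert d.status == "yes"
        for t in fig2:
            _, agrees = displays_and_agrees(d.certificate.ast, t)
            assert agrees

    def test_fig1_no(self, fig1):
        assert decide_agreement(fig1).status == "no"

    def test_single_tree_profile(self):
        t = parse_newick("((a,b),c,(d,e));", 0)
        d = decide_agreement(Profile([t]))
        assert d.status == "yes"
        _, agrees = displays_and_agrees(d.certificate.ast, t)
        assert agrees

    def test_agreement_implies_compatibility(self):
        for p, _ in small_random_profiles(
            25, n_labels=6, subset_size=5, contraction_prob=0.25
        ):
            da = decide_agreement(p)
            if da.status == "yes":
                assert decide_compatibility(p).status == "yes"

    def test_matches_oracle(self):
        for p, _ in small_random_profiles(
            30, n_labels=5, subset_size=4, contraction_prob=0.3
        ):
            d = decide_agreement(p)
            assert (d.status == "yes") == brute_force_ast(p)

    def test_different_resolutions_of_a_star_disagree(self):
        p = Profile([parse_newick("((a,b),(c,d));", 0),
                     parse_newick("((a,c),(b,d));", 1)])
        assert not brute_force_ast(p)
        assert decide_agreement(p).status == "no"


class TestCutFunction:
    def test_self_agreement_maps_each_edge_to_itself(self):
        t = parse_newick("((a,b),c,(d,e));", 0)
        p = Profile([t])
        cf = cut_function(t, p)
        for e in cf.psi:
            assert cf.psi[e] == frozenset({e})

    def test_values_are_cuts_and_distinct(self, fig2):
        ast = decide_agreement(fig2).certificate.ast
        cf = cut_function(ast, fig2)
        display = build_display_graph(fig2)
        values = list(cf.psi.values())
        assert len(set(values)) == len(values)  # injective
        for psi in values:
            # Psi(e) is a cut: its removal disconnects the display graph
            assert len(_components_after(display.graph, psi)) >= 2

    def test_internal_minimal_psi_values_match_a_printed_cut_set(self, fig2):
        ast = normalize_ast(decide_agreement(fig2).certificate.ast, fig2)
        cf = cut_function(ast, fig2)
        internal = {
            cf.psi[e]
            for e in cf.psi
            if e[0] not in ast.leaves and e[1] not in ast.leaves
        }
        from supercut.verify import verify_cutset_certificate

        assert verify_cutset_certificate(fig2, sorted(internal, key=sorted),
                                         agreement=True) == []

    def test_rejects_non_agreeing_tree(self, fig1):
        supertree = decide_compatibility(fig1).certificate.supertree
        with pytest.raises(DomainError):
            cut_function(supertree, fig1)

    def test_vertex_sides_partition_the_display_graph(self, fig2):
        ast = decide_agreement(fig2).certificate.ast
        cf = cut_function(ast, fig2)
        display = build_display_graph(fig2)
        all_vertices = set(display.graph.nodes)
        for e, (vu, vv) in cf.vertex_sides.items():
            assert vu | vv == all_vertices
            assert not vu & vv

    def test_observation2_far_side_labels_stay_together(self):
        for seed in range(8):
            p, truth = random_profile(
                ProfileRecipe(n_labels=6, n_trees=2, subset_size=5,
                              contraction_prob=0.0, seed=seed)
            )
            d = decide_agreement(p)
            if d.status != "yes" or d.certificate.cutset is None:
                continue
            ast = d.certificate.ast
            cf = cut_function(ast, p)
            display = build_display_graph(p)
            for e, (lu, lv) in cf.sides.items():
                comps = _components_after(display.graph, cf.psi[e])
                for t in p:
                    far = t.labels & lv
                    if far:
                        assert sum(1 for c in comps if far & c) == 1


class TestSplitting:
    @staticmethod
    def _first_splittable(p, ast):
        # the ground-truth supertree, cut down to the profile's labels, is
        # an AST of an unperturbed, uncontracted profile; its Psi values
        # need not be minimal
        if not build_display_graph(p).is_connected():
            return None
        if ast.labels != p.label_universe:
            ast = restrict_tree(ast, p.label_universe)
        for t in p:
            _, agrees = displays_and_agrees(ast, t)
            if not agrees:
                return None
        cf = cut_function(ast, p)
        for e in sorted(cf.psi, key=str):
            if cf.is_minimal(e):
                continue
            from supercut.agreement import _partition_by_components

            for u, lx in ((e[0], cf.sides[e][1]), (e[1], cf.sides[e][0])):
                if len(_partition_by_components(cf.display, cf.psi[e], lx)) > 1:
                    return ast, e, u
        return None

    def test_splitting_preserves_agreement(self):
        hits = 0
        for p, truth in small_random_profiles(
            30, n_labels=7, n_trees=3, subset_size=4, contraction_prob=0.0
        ):
            found = self._first_splittable(p, truth)
            if found is None:
                continue
            ast, e, u = found
            s_prime = split_edge_at(ast, e, u, p)
            for t in p:
                _, agrees = displays_and_agrees(s_prime, t)
                assert agrees
            hits += 1
        assert hits >= 3  # the sweep must actually exercise the operation

    def test_split_on_minimal_psi_rejected(self, fig2):
        ast = normalize_ast(decide_agreement(fig2).certificate.ast, fig2)
        cf = cut_function(ast, fig2)
        e = next(iter(cf.psi))
        with pytest.raises(DomainError):
            split_edge_at(ast, e, e[0], fig2)

    def test_normalization_reaches_all_minimal(self):
        for p, _ in small_random_profiles(
            12, n_labels=7, n_trees=3, subset_size=4, contraction_prob=0.0
        ):
            d = decide_agreement(p)
            if d.status != "yes":
                continue
            norm = normalize_ast(d.certificate.ast, p)
            cf = cut_function(norm, p)
            assert all(cf.is_minimal(e) for e in cf.psi)
            for t in p:
                _, agrees = displays_and_agrees(norm, t)
                assert agrees

    def test_observation3_restrictions_survive_the_split(self):
        import itertools

        for p, truth in small_random_profiles(
            20, n_labels=7, n_trees=3, subset_size=4, contraction_prob=0.0
        ):
            found = self._first_splittable(p, truth)
            if found is None:
                continue
            ast, e, u = found
            cf = cut_function(ast, p)
            lv = cf.sides[e][1] if e[0] == u else cf.sides[e][0]
            s_prime = split_edge_at(ast, e, u, p)
            comps = _components_after(cf.display.graph, cf.psi[e])
            for c in comps:
                part = frozenset(x for x in c if x in lv)
                if not part:
                    continue
                for r in (1, min(2, len(part))):
                    for x in itertools.combinations(sorted(part), r):
                        before = restrict_tree(ast, set(x))
                        after = restrict_tree(s_prime, set(x))
                        _, agrees = displays_and_agrees(after, before)
                        assert agrees
            break


class TestOracle:
    def test_single_tree(self):
        p = Profile([parse_newick("((a,b),(c,d));", 0)])
        assert brute_force_ast(p)

    def test_crossing_quartets_no_ast(self):
        quartets, _ = incompatible_fixture()
        assert not brute_force_ast(quartets)

    def test_refinement_without_agreement(self):
        # compatible (star refines to quartet) but not in agreement
        p = Profile([parse_newick("(a,b,c,d);", 0),
                     parse_newick("((a,b),(c,d));", 1)])
        assert not brute_force_ast(p)
        from supercut.compat import brute_force_compatible

        assert brute_force_compatible(p)
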