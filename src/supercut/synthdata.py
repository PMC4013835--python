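"""Worked-example fixtures and seeded random profile generators.

The two figure fixtures are reconstructions of the worked examples: their
topologies are pinned down by the printed cuts and splits, and every
constructor re-verifies the full printed certificate (cut legality,
minimality, parallelism, completeness, induced splits) before handing the
profile out -- a transcription error is a hard :class:`FixtureError`, never
silently patched.

Random profiles are drawn by restricting a random binary supertree to label
subsets, optionally contracting internal edges (compatible but possibly
non-agreeing inputs) or swapping two leaf labels in one tree (likely
incompatible).  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

from .errors import DomainError, FixtureError
from .graphs import (
    Cut,
    CutSet,
    build_display_graph,
    classify_cut,
    cut_to_split,
    cuts_parallel,
    is_minimal_cut,
)
from .phylo import PhyloTree, Profile, Split, edge_key, restrict_tree

__all__ = [
    "ProfileRecipe",
    "fig1_profile",
    "fig1_example_cuts",
    "fig2_profile",
    "fig2_example_cuts",
    "random_profile",
    "random_binary_tree",
    "incompatible_fixture",
]


def _tree(edges, leaves) -> PhyloTree:
    g = nx.Graph()
    g.add_edges_from(edges)
    return PhyloTree(g, leaves)


def _verify_cutset(profile, cuts, splits=None, per_tree_limit=None, name=""):
    from .compat import cutset_is_complete  # local import avoids a cycle

    display = build_display_graph(profile)
    for c in cuts:
        if not is_minimal_cut(display.graph, c.edges):
            raise FixtureError(f"{name}: {c!r} is not a minimal cut")
        legal, nice = classify_cut(display, c)
        if not (legal and nice):
            raise FixtureError(f"{name}: {c!r} legal={legal} nice={nice}")
        if per_tree_limit is not None:
            for i in range(len(profile.trees)):
                if len(display.tree_slice(c.edges, i)) > per_tree_limit:
                    raise FixtureError(
                        f"{name}: {c!r} has more than {per_tree_limit} "
                        f"edge(s) of tree {i}"
                    )
    for i, c1 in enumerate(cuts):
        for c2 in cuts[i + 1 :]:
            if not cuts_parallel(display.graph, c1, c2):
                raise FixtureError(f"{name}: {c1!r} and {c2!r} not parallel")
    if not cutset_is_complete(display, cuts):
        raise FixtureError(f"{name}: cut set is not complete")
    if splits is not None:
        got = [cut_to_split(display, c) for c in cuts]
        if got != list(splits):
            raise FixtureError(f"{name}: induced splits {got} != printed {splits}")


# ---------------------------------------------------------------------------
# Figure 1: compatible but not agreeing


def fig1_example_cuts() -> CutSet:
    """The four printed cuts F1..F4 of the first worked example, in their
    printed order."""
    return CutSet(
        [
            Cut([("1", "2"), ("5", "6")]),
            Cut([("2", "3"), ("6", "7"), ("5", "6")]),
            Cut([("4", "5"), ("1", "2"), ("1", "c")]),
            Cut([("6", "7"), ("2", "f")]),
        ]
    )


@lru_cache(maxsize=None)
def fig1_profile() -> Profile:
    """The two-tree figure profile: compatible, but with no agreement
    supertree.  Internal vertex ids 1-3 (first tree) and 4-7 (second) match
    the ids the worked examples use in their cut lists."""
    t1 = _tree(
        [
            ("1", "a"), ("1", "b"), ("1", "c"), ("1", "2"),
            ("2", "f"), ("2", "3"), ("3", "d"), ("3", "e"),
        ],
        ["a", "b", "c", "d", "e", "f"],
    )
    t2 = _tree(
        [
            ("4", "a"), ("4", "b"), ("4", "5"), ("5", "c"),
            ("5", "6"), ("6", "d"), ("6", "7"), ("7", "f"), ("7", "g"),
        ],
        ["a", "b", "c", "d", "f", "g"],
    )
    profile = Profile([t1, t2])
    printed_splits = [
        Split("abc", "defg"),
        Split("abcfg", "de"),
        Split("ab", "cdefg"),
        Split("abcde", "fg"),
    ]
    _verify_cutset(
        profile, list(fig1_example_cuts()), splits=printed_splits, name="fig1"
    )
    return profile


# ---------------------------------------------------------------------------
# Figure 2: agreeing


def fig2_example_cuts() -> CutSet:
    """The three printed cuts of the agreement worked example."""
    return CutSet(
        [
            Cut([("1", "2"), ("4", "5")]),
            Cut([("1", "2"), ("5", "6")]),
            Cut([("2", "3"), ("6", "d")]),
        ]
    )


@lru_cache(maxsize=None)
def fig2_profile() -> Profile:
    """A two-tree profile with an agreement supertree.

    Synthetic reconstruction: the figure itself is not reproduced in the
    extracted text, so the topology was rebuilt from the printed cut lists
    (internal ids 1-3 and 4-6, a shared leaf ``d`` on vertex 6); the
    constructor verifies every printed predicate and that an agreement
    supertree exists, so any reconstruction accepted here is a valid
    witness of the worked example's claims.
    """
    t1 = _tree(
        [
            ("1", "a"), ("1", "b"), ("1", "2"), ("2", "c"),
            ("2", "3"), ("3", "d"), ("3", "e"),
        ],
        ["a", "b", "c", "d", "e"],
    )
    t2 = _tree(
        [
            ("4", "a"), ("4", "b"), ("4", "5"), ("5", "g"),
            ("5", "6"), ("6", "d"), ("6", "f"),
        ],
        ["a", "b", "d", "f", "g"],
    )
    profile = Profile([t1, t2])
    _verify_cutset(
        profile, list(fig2_example_cuts()), per_tree_limit=1, name="fig2"
    )
    from .agreement import decide_agreement

    if decide_agreement(profile).status != "yes":
        raise FixtureError("fig2: no agreement supertree found")
    return profile


# ---------------------------------------------------------------------------
# Random profiles


@dataclass(frozen=True)
class ProfileRecipe:
    """Deterministic recipe: identical recipe + seed gives a byte-identical
    profile.

    ``subset_size`` is the number of labels sampled for each input tree
    (one int for all trees, or a tuple per tree); ``contraction_prob`` is
    the independent probability of contracting each internal edge of a
    restricted tree; ``perturb`` is ``None`` or ``"swap"`` (swap two leaf
    labels in one tree, breaking compatibility with high probability).
    """

    n_labels: int = 8
    n_trees: int = 3
    subset_size: int | tuple = 6
    contraction_prob: float = 0.0
    perturb: str | None = None
    seed: int = 0


def _labels(n: int) -> list[str]:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if n <= len(alphabet):
        return list(alphabet[:n])
    return [f"x{i:03d}" for i in range(n)]


def random_binary_tree(labels, rng: random.Random, prefix: str = "g") -> PhyloTree:
    """Random binary topology by sequential attachment at a uniformly
    chosen existing edge (not uniform over labelled topologies)."""
    labels = sorted(labels)
    g = nx.Graph()
    if len(labels) == 1:
        g.add_node(labels[0])
        return PhyloTree(g, labels)
    if len(labels) == 2:
        g.add_edge(labels[0], labels[1])
        return PhyloTree(g, labels)
    g.add_edges_from((f"{prefix}.0", x) for x in labels[:3])
    for i, label in enumerate(labels[3:], start=1):
        u, v = rng.choice(sorted((edge_key(a, b) for a, b in g.edges()), key=str))
        w = f"{prefix}.{i}"
        g.remove_edge(u, v)
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, label)
    return PhyloTree(g, labels)


def _renamespace(tree: PhyloTree, tree_index: int) -> PhyloTree:
    internal = sorted(tree.internal_vertices(), key=str)
    mapping = {v: f"t{tree_index}.{i}" for i, v in enumerate(internal, start=1)}
    return PhyloTree(nx.relabel_nodes(tree.graph, mapping), tree.leaves)


def _contract_random_edges(tree: PhyloTree, prob: float, rng: random.Random) -> PhyloTree:
    """Contract each internal edge independently with probability ``prob``
    (all coin flips decided up front, then merged as one quotient)."""
    chosen = [e for e in sorted(tree.internal_edges(), key=str) if rng.random() < prob]
    if not chosen:
        return tree
    parent = {v: v for v in tree.graph}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in chosen:
        ru, rv = find(u), find(v)
        if ru != rv:
            ru, rv = sorted((ru, rv), key=str)
            parent[rv] = ru
    g = nx.Graph()
    g.add_nodes_from({find(v) for v in tree.graph})
    for u, v in tree.graph.edges():
        ru, rv = find(u), find(v)
        if ru != rv:
            g.add_edge(ru, rv)
    return PhyloTree(g, tree.leaves)


def random_profile(recipe: ProfileRecipe) -> tuple[Profile, PhyloTree | None]:
    """Draw ``(profile, ground_truth)``; the ground-truth supertree is
    returned only when no perturbation was applied (it displays every
    input, and agrees with every input when nothing was contracted)."""
    rng = random.Random(recipe.seed)
    labels = _labels(recipe.n_labels)
    supertree = random_binary_tree(labels, rng)
    sizes = (
        [recipe.subset_size] * recipe.n_trees
        if isinstance(recipe.subset_size, int)
        else list(recipe.subset_size)
    )
    if len(sizes) != recipe.n_trees:
        raise DomainError("one subset size per tree required")
    trees = []
    for i, size in enumerate(sizes):
        if size < 1:
            raise DomainError("subset size must be at least 1")
        if size > recipe.n_labels:
            raise DomainError("subset size exceeds the label count")
        subset = sorted(rng.sample(labels, size))
        t = restrict_tree(supertree, subset)
        if recipe.contraction_prob > 0:
            t = _contract_random_edges(t, recipe.contraction_prob, rng)
        trees.append(_renamespace(t, i))
    if recipe.perturb == "swap":
        idx = rng.randrange(len(trees))
        t = trees[idx]
        if len(t.leaves) >= 2:
            a, b = rng.sample(sorted(t.leaves), 2)
            trees[idx] = PhyloTree(
                nx.relabel_nodes(t.graph, {a: b, b: a}), t.leaves
            )
    elif recipe.perturb is not None:
        raise DomainError(f"unknown perturbation mode {recipe.perturb!r}")
    profile = Profile(trees)
    truth = supertree if recipe.perturb is None else None
    return profile, truth


# ---------------------------------------------------------------------------
# Incompatible fixtures


@lru_cache(maxsize=None)
def incompatible_fixture() -> tuple[Profile, Profile]:
    """Two incompatible profiles: the classic crossing quartet pair
    ab|cd / ac|bd, and a three-quartet 5-label profile whose members are
    pairwise compatible but jointly incompatible."""
    from .phylo import parse_newick

    quartets = Profile(
        [
            parse_newick("((a,b),(c,d));", 0),
            parse_newick("((a,c),(b,d));", 1),
        ]
    )
    triple = Profile(
        [
            parse_newick("((a,b),(c,d));", 0),
            parse_newick("((b,c),(d,e));", 1),
            parse_newick("((c,e),(a,d));", 2),
        ]
    )
    from .compat import brute_force_compatible

    for name, p in (("quartets", quartets), ("triple", triple)):
        if brute_force_compatible(p):
            raise FixtureError(f"incompatible fixture {name} is compatible")
    return quartets, triple
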