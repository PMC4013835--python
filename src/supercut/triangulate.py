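"""Chordality, clique trees, legal/restricted triangulations, and the
construction of a legal triangulation from a complete cut set.

A triangulation of the display graph is *legal* when (LT1) no clique mixes
an internal display edge with any other display edge and (LT2) no fill-in
edge touches a leaf; profiles are compatible exactly when such a
triangulation exists.  The constructive bridge from the cut world goes
through per-cut separator pairs ``(X_F, Y_F)`` and an interpolating family
``O_F``; saturating the display graph with those families (plus each leaf's
neighborhood) yields a legal triangulation directly, without building a
supertree first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .compat import cutset_is_complete, minimize_cutset
from .errors import DomainError, InternalConsistencyError
from .graphs import (
    Cut,
    CutSet,
    DisplayGraph,
    _components_after,
    classify_cut,
    cuts_parallel,
    is_minimal_cut,
)
from .phylo import edge_key

__all__ = [
    "Triangulation",
    "CliqueTree",
    "CutSeparatorPair",
    "is_chordal",
    "clique_tree",
    "saturate",
    "is_legal_triangulation",
    "is_restricted_triangulation",
    "build_cut_separator_pairs",
    "cuts_to_triangulation",
]


@dataclass
class Triangulation:
    host: nx.Graph
    graph: nx.Graph
    families: list[frozenset] = field(default_factory=list)

    @property
    def fill_in(self) -> set:
        return {
            edge_key(u, v)
            for u, v in self.graph.edges()
            if not self.host.has_edge(u, v)
        }

    @property
    def chordal(self) -> bool:
        ok, _ = is_chordal(self.graph)
        return ok


@dataclass
class CliqueTree:
    tree: nx.Graph  # nodes are frozensets (the maximal cliques)

    def cliques(self) -> list[frozenset]:
        return list(self.tree.nodes)

    def edge_separators(self) -> set[frozenset]:
        return {frozenset(x & y) for x, y in self.tree.edges()}


# ---------------------------------------------------------------------------
# Chordality via maximum cardinality search


def is_chordal(g: nx.Graph):
    """``(True, elimination_order)`` or ``(False, chordless_cycle)``.

    Maximum-cardinality search followed by the fill check; on failure a
    chordless cycle of length >= 4 is extracted as a witness.
    """
    order = _mcs_order(g)
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        earlier = [w for w in g.neighbors(v) if pos[w] < pos[v]]
        if len(earlier) <= 1:
            continue
        m = max(earlier, key=lambda w: pos[w])
        for w in earlier:
            if w is m:
                continue
            if not g.has_edge(w, m):
                return (False, _chordless_cycle(g, v, w, m))
    return (True, list(reversed(order)))


def _mcs_order(g: nx.Graph) -> list:
    weights = {v: 0 for v in g}
    order = []
    unvisited = set(g.nodes)
    while unvisited:
        v = max(sorted(unvisited, key=str), key=lambda x: weights[x])
        order.append(v)
        unvisited.discard(v)
        for w in g.neighbors(v):
            if w in unvisited:
                weights[w] += 1
    return order


def _chordless_cycle(g: nx.Graph, v, w, m) -> list:
    """A chordless cycle through ``v`` and its non-adjacent neighbors
    ``w, m``: a shortest ``w``-``m`` path avoiding ``N[v] - {w, m}``."""
    forbidden = (set(g.neighbors(v)) | {v}) - {w, m}
    h = g.subgraph([x for x in g if x not in forbidden])
    path = nx.shortest_path(h, w, m)
    # a shortest path may still carry chords in g via vertices adjacent in g
    # but not in h; shrink to an induced path
    path = _induced_path(g, path)
    return [v] + path


def _induced_path(g: nx.Graph, path: list) -> list:
    changed = True
    while changed:
        changed = False
        for i in range(len(path)):
            for j in range(len(path) - 1, i + 1, -1):
                if j > i + 1 and g.has_edge(path[i], path[j]):
                    path = path[: i + 1] + path[j:]
                    changed = True
                    break
            if changed:
                break
    return path


def clique_tree(h: nx.Graph) -> CliqueTree:
    """Clique tree of a connected chordal graph: maximum-weight spanning
    tree of the clique-intersection graph; coherence is verified."""
    ok, _ = is_chordal(h)
    if not ok:
        raise DomainError("clique tree requires a chordal graph")
    if h.number_of_nodes() == 0:
        raise DomainError("empty graph")
    if not nx.is_connected(h):
        raise DomainError("clique tree requires a connected graph")
    cliques = [frozenset(c) for c in nx.chordal_graph_cliques(h)]
    t = nx.Graph()
    t.add_nodes_from(cliques)
    for c1, c2 in itertools.combinations(cliques, 2):
        w = len(c1 & c2)
        if w > 0:
            t.add_edge(c1, c2, weight=w)
    if len(cliques) > 1:
        t = nx.maximum_spanning_tree(t)
        t.add_nodes_from(cliques)
    for v in h:
        nodes = [c for c in cliques if v in c]
        if not nx.is_connected(t.subgraph(nodes)):
            raise InternalConsistencyError(
                f"coherence violated for vertex {v!r}"
            )
    return CliqueTree(t)


def saturate(g: nx.Graph, families) -> nx.Graph:
    """``G_F``: make each family of vertices a clique (idempotent, never
    removes edges)."""
    out = g.copy()
    for fam in families:
        fam = list(fam)
        for v in fam:
            if v not in g:
                raise DomainError(f"family member {v!r} not a vertex")
        for u, v in itertools.combinations(fam, 2):
            out.add_edge(u, v)
    return out


# ---------------------------------------------------------------------------
# Legality checks


def _check_supergraph(g: nx.Graph, h: nx.Graph) -> None:
    if set(g.nodes) != set(h.nodes):
        raise DomainError("triangulation must keep the vertex set")
    for u, v in g.edges():
        if not h.has_edge(u, v):
            raise DomainError("triangulation must keep every host edge")


def is_legal_triangulation(display: DisplayGraph, h: nx.Graph) -> bool:
    """Chordal + (LT1) no clique holds an internal display edge together
    with another display edge + (LT2) no fill-in edge touches a leaf."""
    _check_supergraph(display.graph, h)
    ok, _ = is_chordal(h)
    if not ok:
        return False
    for u, v in h.edges():
        if not display.graph.has_edge(u, v):
            if display.is_leaf(u) or display.is_leaf(v):
                return False  # LT2
    display_edges = [edge_key(u, v) for u, v in display.graph.edges()]
    for c in nx.chordal_graph_cliques(h):
        inside = [e for e in display_edges if e[0] in c and e[1] in c]
        if len(inside) >= 2 and any(display.is_internal_edge(e) for e in inside):
            return False  # LT1
    return True


def is_restricted_triangulation(elig, h: nx.Graph) -> bool:
    """Chordal + every fill-in edge valid: its two endpoints (display
    edges) never both belong to one input tree's line graph."""
    _check_supergraph(elig.graph, h)
    ok, _ = is_chordal(h)
    if not ok:
        return False
    prov = elig.display.provenance
    for e1, e2 in h.edges():
        if not elig.graph.has_edge(e1, e2):
            if prov[edge_key(*e1)] & prov[edge_key(*e2)]:
                return False
    return True


# ---------------------------------------------------------------------------
# Cut set -> legal triangulation


@dataclass
class CutSeparatorPair:
    """The per-cut separator pair ``(X_F, Y_F)`` with the interpolation
    family ``O_F``; ``pairs[i] = (x_i, y_i)`` are the internal edges this
    cut differentiates via rule 1(a), ``shared`` is ``F_cap``."""

    cut: Cut
    side_a: frozenset  # component A_F of display - F
    side_b: frozenset
    pairs: list  # [(x_i, y_i)] with x_i in A_F, y_i in B_F
    shared: frozenset  # z-vertices (in both X_F and Y_F)
    sole_slice: frozenset  # F-hat: edges that are sole slice of their tree
    slices: dict  # tree index -> slice

    @property
    def x_set(self) -> frozenset:
        return frozenset(x for x, _ in self.pairs) | self.shared

    @property
    def y_set(self) -> frozenset:
        return frozenset(y for _, y in self.pairs) | self.shared

    @property
    def f_union(self) -> frozenset:
        return self.x_set | self.y_set

    @property
    def f_cap(self) -> frozenset:
        return self.x_set & self.y_set

    def o_family(self) -> list[frozenset]:
        xs = [x for x, _ in self.pairs]
        ys = [y for _, y in self.pairs]
        m = len(xs)
        return [
            frozenset(xs[:j]) | frozenset(ys[j - 1 :]) | self.shared
            for j in range(1, m + 1)
        ]

    def differentiates(self, e) -> bool:
        x, y = e
        return (x in self.x_set and y in self.y_set) or (
            y in self.x_set and x in self.y_set
        )


def _validate_cutset(display: DisplayGraph, cutset: CutSet) -> None:
    cuts = list(cutset)
    for c in cuts:
        if not is_minimal_cut(display.graph, c.edges):
            raise DomainError(f"{c!r} is not a minimal cut")
        legal, _ = classify_cut(display, c)
        if not legal:
            raise DomainError(f"{c!r} is not legal")
    for c1, c2 in itertools.combinations(cuts, 2):
        if not cuts_parallel(display.graph, c1, c2):
            raise DomainError(f"cuts not pairwise parallel: {c1!r} / {c2!r}")
    if not cutset_is_complete(display, cuts):
        raise DomainError("cut set is not complete")
    for c in cuts:
        rest = [x for x in cuts if x.edges != c.edges]
        if cutset_is_complete(display, rest):
            raise DomainError(
                "a proper subset is still complete; minimize the cut set first"
            )


def build_cut_separator_pairs(
    display: DisplayGraph, cutset: CutSet
) -> list[CutSeparatorPair]:
    """The ordered ``(X_F, Y_F)`` construction.

    Processing cuts in the given (fixed) order: each sole-slice internal
    edge not yet differentiated contributes an ``(x_i, y_i)`` pair (rule
    1a); one already differentiated by an earlier cut ``I`` contributes its
    endpoint in the unique component of ``display - I`` meeting ``F`` to
    both sides (rule 1b); sole-slice leaf edges contribute their non-leaf
    endpoint to both sides (rule 2); multi-edge tree slices contribute
    their common endpoint to both sides (rule 3).
    """
    _validate_cutset(display, cutset)
    k = len(display.profile.trees)
    built: list[CutSeparatorPair] = []
    for c in cutset:
        slices = {i: display.tree_slice(c.edges, i) for i in range(k)}
        sole = frozenset(
            e for i, sl in slices.items() if len(sl) == 1 for e in sl
        )
        comps = _components_after(display.graph, c.edges)
        comps.sort(key=lambda s: min(map(str, s)))
        side_a, side_b = frozenset(comps[0]), frozenset(comps[1])
        pairs: list = []
        shared: set = set()
        for e in sorted(sole, key=str):
            if display.is_internal_edge(e):
                prior = next((p for p in built if p.differentiates(e)), None)
                if prior is None:
                    x = e[0] if e[0] in side_a else e[1]
                    y = e[1] if x == e[0] else e[0]
                    if x not in side_a or y not in side_b:
                        raise InternalConsistencyError(
                            f"cut edge {e} does not span the two components"
                        )
                    pairs.append((x, y))
                else:
                    q = _component_meeting(display, prior.cut, c)
                    in_q = [v for v in e if v in q]
                    if len(in_q) != 1:
                        raise InternalConsistencyError(
                            f"edge {e} has {len(in_q)} endpoints in the "
                            "unique component meeting the later cut"
                        )
                    shared.add(in_q[0])
            else:
                u, v = e
                shared.add(v if display.is_leaf(u) else u)
        for i, sl in slices.items():
            if len(sl) > 1:
                common = set(next(iter(sl)))
                for e in sl:
                    common &= set(e)
                if len(common) != 1:
                    raise InternalConsistencyError(
                        f"multi-edge slice of tree {i} lacks a unique "
                        "common endpoint"
                    )
                shared.add(common.pop())
        if not pairs:
            raise InternalConsistencyError(
                f"cut {c!r} differentiates no internal edge (m = 0); the "
                "cut set was not minimal"
            )
        built.append(
            CutSeparatorPair(
                cut=c,
                side_a=side_a,
                side_b=side_b,
                pairs=pairs,
                shared=frozenset(shared),
                sole_slice=sole,
                slices=slices,
            )
        )
    for e in display.edges():
        if display.is_internal_edge(e) and not any(
            p.differentiates(e) for p in built
        ):
            raise InternalConsistencyError(
                f"internal display edge {e} is differentiated by no cut"
            )
    return built


def _component_meeting(display: DisplayGraph, earlier: Cut, later: Cut) -> set:
    """The unique component of ``display - earlier`` containing edges of
    ``later`` (unique because the two cuts are parallel)."""
    comps = _components_after(display.graph, earlier.edges)
    hits = [
        c for c in comps if any(u in c and v in c for u, v in later.edges)
    ]
    if len(hits) != 1:
        raise InternalConsistencyError(
            "expected exactly one component meeting the later cut; the "
            "cuts are not parallel"
        )
    return hits[0]


def cuts_to_triangulation(display: DisplayGraph, cutset: CutSet) -> Triangulation:
    """Saturate the display graph with the leaf neighborhoods and every
    ``{X_F, Y_F}`` and ``O_F`` family; the result is verified to be a legal
    triangulation before it is returned."""
    pairs = build_cut_separator_pairs(display, cutset)
    families: list[frozenset] = [
        frozenset(display.graph.neighbors(leaf)) for leaf in sorted(display.leaves)
    ]
    for p in pairs:
        families.append(p.x_set)
        families.append(p.y_set)
        families.extend(p.o_family())
    h = saturate(display.graph, families)
    for p in pairs:  # spot check: each F-union must induce a clean chordal piece
        sub = h.subgraph(p.f_union)
        ok, _ = is_chordal(sub)
        if not ok:
            raise InternalConsistencyError(
                "F-union induced subgraph is not chordal"
            )
    if not is_legal_triangulation(display, h):
        raise InternalConsistencyError(
            "saturation of a valid cut set failed the legal-triangulation check"
        )
    return Triangulation(host=display.graph, graph=h, families=families)
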