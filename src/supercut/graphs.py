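"""Display graph and edge-label-intersection-graph (ELIG) machinery.

The display graph ``G(P)`` of a profile is the union of the input trees with
equal-label leaves identified.  Its line graph, the ELIG ``LG(P)``, has the
display edges as vertices, adjacent when the edges share an endpoint.  Cut
predicates on ``G(P)`` -- minimal, legal ("per tree, all cut edges share a
vertex"), nice ("legal, and every component keeps an edge"), parallel -- and
the corresponding separator predicates on ``LG(P)`` are the building blocks
of the compatibility and agreement characterizations.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import networkx as nx

from .errors import DomainError, ResourceExhaustedError
from .phylo import PhyloTree, Profile, Split, edge_key

__all__ = [
    "DisplayGraph",
    "ELIG",
    "Cut",
    "CutSet",
    "build_display_graph",
    "build_elig",
    "is_minimal_cut",
    "enumerate_minimal_cuts",
    "classify_cut",
    "cuts_parallel",
    "is_minimal_separator",
    "full_components",
    "enumerate_minimal_separators",
    "separators_parallel",
    "separator_is_legal",
    "cut_to_split",
    "canonical_cut_sort_key",
]

Edge = tuple
EdgeSet = frozenset


# ---------------------------------------------------------------------------
# Containers


class DisplayGraph:
    """``G(P)`` with per-edge provenance (which input tree(s) own the edge).

    Provenance is a frozenset of tree indices; it is a singleton except in
    the degenerate corner where two two-leaf trees coincide on the same
    leaf pair.
    """

    def __init__(self, profile: Profile):
        self.profile = profile
        self.leaves = profile.label_universe
        g = nx.Graph()
        for label in self.leaves:
            g.add_node(label)
        provenance: dict[Edge, set[int]] = {}
        for i, t in enumerate(profile):
            for v in t.graph.nodes:
                g.add_node(v)
            for u, v in t.graph.edges():
                e = edge_key(u, v)
                g.add_edge(*e)
                provenance.setdefault(e, set()).add(i)
        self.graph = g
        self.provenance = {e: frozenset(s) for e, s in provenance.items()}

    def is_leaf(self, v) -> bool:
        return v in self.leaves

    def is_internal_edge(self, e: Edge) -> bool:
        u, v = e
        return u not in self.leaves and v not in self.leaves

    def edges(self) -> list[Edge]:
        return sorted(edge_key(u, v) for u, v in self.graph.edges())

    def tree_slice(self, edges: Iterable[Edge], tree_index: int) -> frozenset:
        """``F ∩ E(T_i)`` for an edge set ``F``."""
        return frozenset(
            e for e in edges if tree_index in self.provenance[edge_key(*e)]
        )

    def components(self) -> list[frozenset]:
        return [frozenset(c) for c in nx.connected_components(self.graph)]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


class ELIG:
    """The line graph of the display graph, with per-tree membership."""

    def __init__(self, display: DisplayGraph):
        self.display = display
        self.graph = nx.line_graph(display.graph)
        # normalize node ids to canonical edge keys
        mapping = {n: edge_key(*n) for n in self.graph.nodes}
        self.graph = nx.relabel_nodes(self.graph, mapping, copy=True)
        for e in display.edges():
            if e not in self.graph:
                self.graph.add_node(e)

    def tree_members(self, tree_index: int) -> frozenset:
        return frozenset(
            e for e in self.graph.nodes if tree_index in self.display.provenance[e]
        )


class Cut:
    """A set of display-graph edges with cached classification flags."""

    __slots__ = ("edges", "minimal", "legal", "nice")

    def __init__(self, edges: Iterable[Edge], minimal=None, legal=None, nice=None):
        self.edges = frozenset(edge_key(*e) for e in edges)
        self.minimal = minimal
        self.legal = legal
        self.nice = nice

    def __eq__(self, other):
        return isinstance(other, Cut) and self.edges == other.edges

    def __hash__(self):
        return hash(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)

    def sort_key(self):
        return canonical_cut_sort_key(self.edges)

    def __repr__(self):
        return "Cut({})".format(
            ", ".join("{%s,%s}" % (u, v) for u, v in sorted(self.edges))
        )


def canonical_cut_sort_key(edges: Iterable[Edge]):
    """Canonical order for cuts: by sorted edge lists (then by size)."""
    items = sorted(tuple(map(str, e)) for e in edges)
    return (len(items), items)


class CutSet:
    """An ordered collection of cuts; the order is semantic (it is used by
    the cuts-to-triangulation construction)."""

    def __init__(self, cuts: Sequence[Cut]):
        self.cuts = list(cuts)

    @classmethod
    def canonical(cls, cuts: Iterable[Cut]) -> "CutSet":
        return cls(sorted(set(cuts), key=Cut.sort_key))

    def __iter__(self):
        return iter(self.cuts)

    def __len__(self):
        return len(self.cuts)

    def __getitem__(self, i):
        return self.cuts[i]

    def edge_sets(self) -> list[frozenset]:
        return [c.edges for c in self.cuts]


# ---------------------------------------------------------------------------
# Construction


def build_display_graph(profile: Profile) -> DisplayGraph:
    return DisplayGraph(profile)


def build_elig(display: DisplayGraph) -> ELIG:
    return ELIG(display)


# ---------------------------------------------------------------------------
# Cut predicates


def _check_edges(g: nx.Graph, edges: Iterable[Edge]) -> frozenset:
    es = frozenset(edge_key(*e) for e in edges)
    for u, v in es:
        if not g.has_edge(u, v):
            raise DomainError(f"edge {{{u},{v}}} not in graph")
    return es


def _components_after(g: nx.Graph, edges: frozenset) -> list[set]:
    h = nx.restricted_view(g, [], edges)
    return [set(c) for c in nx.connected_components(h)]


def is_minimal_cut(g: nx.Graph, f: Iterable[Edge]) -> bool:
    """True iff ``g - f`` has exactly two components and every edge of ``f``
    joins the two sides (equivalently: no proper subset disconnects)."""
    if not nx.is_connected(g):
        raise DomainError("minimal-cut test requires a connected graph")
    es = _check_edges(g, f)
    if not es:
        return False
    comps = _components_after(g, es)
    if len(comps) != 2:
        return False
    side_a = comps[0]
    for u, v in es:
        if (u in side_a) == (v in side_a):
            return False
    return True


def enumerate_minimal_cuts(g: nx.Graph, max_vertices: int = 18) -> list[Cut]:
    """All minimal cuts, as boundaries of connected vertex bipartitions.

    ``delta(S)`` is a minimal cut iff both ``S`` and ``V - S`` induce
    connected subgraphs; enumeration is exhaustive over bipartitions and
    therefore exponential, guarded by ``max_vertices``.
    """
    if not nx.is_connected(g):
        raise DomainError("cut enumeration requires a connected graph")
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n > max_vertices:
        raise ResourceExhaustedError(
            f"{n} vertices exceeds guard {max_vertices}; raise max_vertices "
            "to force enumeration"
        )
    if n < 2:
        return []
    anchor, rest = nodes[0], nodes[1:]
    cuts = []
    for bits in range(2 ** (n - 1)):
        side = {anchor}
        for i, v in enumerate(rest):
            if bits >> i & 1:
                side.add(v)
        if len(side) == n:
            continue
        other = set(nodes) - side
        if not nx.is_connected(g.subgraph(side)):
            continue
        if not nx.is_connected(g.subgraph(other)):
            continue
        boundary = frozenset(
            edge_key(u, v) for u, v in nx.edge_boundary(g, side, other)
        )
        cuts.append(Cut(boundary, minimal=True))
    return sorted(set(cuts), key=Cut.sort_key)


def classify_cut(display: DisplayGraph, f: Cut | Iterable[Edge]) -> tuple[bool, bool]:
    """``(legal, nice)`` for an edge set of the display graph.

    Legal: for every input tree, its edges in the cut are incident on a
    common vertex.  Nice: legal, and every component of ``G(P) - F`` has at
    least one edge.
    """
    edges = f.edges if isinstance(f, Cut) else frozenset(edge_key(*e) for e in f)
    _check_edges(display.graph, edges)
    legal = True
    for i in range(len(display.profile.trees)):
        sl = display.tree_slice(edges, i)
        if len(sl) >= 2:
            common = None
            for e in sl:
                common = set(e) if common is None else common & set(e)
            if not common:
                legal = False
                break
    if not legal:
        return (False, False)
    comps = _components_after(display.graph, edges)
    nice = all(
        any(
            edge_key(u, v) not in edges
            for u in c
            for v in display.graph.neighbors(u)
        )
        for c in comps
    )
    return (True, nice)


def cuts_parallel(g: nx.Graph, f1, f2) -> bool:
    """Minimal cuts ``F`` and ``F'`` are parallel iff ``g - F`` has at most
    one component containing edges of ``F'`` (symmetric for minimal cuts;
    both directions are computed and asymmetry raises)."""
    e1 = f1.edges if isinstance(f1, Cut) else frozenset(edge_key(*e) for e in f1)
    e2 = f2.edges if isinstance(f2, Cut) else frozenset(edge_key(*e) for e in f2)
    if not is_minimal_cut(g, e1) or not is_minimal_cut(g, e2):
        raise DomainError("parallelism is defined for minimal cuts only")
    fwd = _parallel_one_way(g, e1, e2)
    bwd = _parallel_one_way(g, e2, e1)
    if fwd != bwd:  # must not happen for minimal cuts; surface loudly
        raise DomainError(
            f"asymmetric parallelism between minimal cuts {sorted(e1)} / {sorted(e2)}"
        )
    return fwd


def _parallel_one_way(g: nx.Graph, f: frozenset, fprime: frozenset) -> bool:
    comps = _components_after(g, f)
    hit = 0
    for c in comps:
        if any(u in c and v in c for u, v in fprime):
            hit += 1
    return hit <= 1


# ---------------------------------------------------------------------------
# Separator predicates (on the ELIG, or any graph)


def full_components(g: nx.Graph, u: Iterable) -> tuple[list[set], int]:
    """Components of ``g - U`` and how many of them are full (see every
    member of ``U``)."""
    us = set(u)
    for v in us:
        if v not in g:
            raise DomainError(f"vertex {v!r} not in graph")
    h = g.subgraph([v for v in g if v not in us])
    comps = [set(c) for c in nx.connected_components(h)]
    nfull = 0
    for c in comps:
        if all(any(w in c for w in g.neighbors(v)) for v in us):
            nfull += 1
    return comps, nfull


def is_minimal_separator(g: nx.Graph, u: Iterable) -> bool:
    """True iff ``g - U`` has at least two full components."""
    us = set(u)
    if not us or len(us) >= g.number_of_nodes():
        return False
    _, nfull = full_components(g, us)
    return nfull >= 2


def enumerate_minimal_separators(g: nx.Graph) -> list[frozenset]:
    """All minimal separators, by neighborhood expansion: seed with the
    separators close to each vertex (``N(C)`` for components ``C`` of
    ``G - N[v]``) and close under the substitution step, which is known to
    reach every minimal separator.  Output in canonical sorted order."""
    if g.number_of_nodes() == 0:
        return []
    seps: set[frozenset] = set()
    queue: list[frozenset] = []

    def components_minus(removed: set):
        h = g.subgraph([v for v in g if v not in removed])
        return nx.connected_components(h)

    def offer(s: frozenset):
        if s and s not in seps and is_minimal_separator(g, s):
            seps.add(s)
            queue.append(s)

    for v in g:
        closed = set(g.neighbors(v)) | {v}
        for c in components_minus(closed):
            offer(frozenset(_neighborhood(g, c)))
    while queue:
        s = queue.pop()
        for x in s:
            removed = set(s) | set(g.neighbors(x)) | {x}
            for c in components_minus(removed):
                offer(frozenset(_neighborhood(g, c)))
    return sorted(seps, key=lambda s: (len(s), sorted(map(str, s))))


def _neighborhood(g: nx.Graph, c) -> set:
    c = set(c)
    out = set()
    for v in c:
        out.update(w for w in g.neighbors(v) if w not in c)
    return out


def _brute_force_minimal_separators(g: nx.Graph, max_vertices: int = 12) -> list[frozenset]:
    """Exhaustive reference enumeration over all vertex subsets (full-
    component criterion); independent oracle for the expansion algorithm."""
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n > max_vertices:
        raise ResourceExhaustedError(f"{n} vertices exceeds guard {max_vertices}")
    out = []
    for r in range(1, max(n - 1, 0)):
        for combo in itertools.combinations(nodes, r):
            if is_minimal_separator(g, combo):
                out.append(frozenset(combo))
    return sorted(out, key=lambda s: (len(s), sorted(map(str, s))))


def separators_parallel(g: nx.Graph, u1: Iterable, u2: Iterable) -> bool:
    """Minimal separators are parallel iff ``g - U`` has at most one
    component meeting ``U'`` (and symmetrically)."""
    s1, s2 = frozenset(u1), frozenset(u2)
    if not is_minimal_separator(g, s1) or not is_minimal_separator(g, s2):
        raise DomainError("parallelism is defined for minimal separators only")
    return _sep_parallel_one_way(g, s1, s2) and _sep_parallel_one_way(g, s2, s1)


def _sep_parallel_one_way(g: nx.Graph, u: frozenset, uprime: frozenset) -> bool:
    comps, _ = full_components(g, u)
    hit = sum(1 for c in comps if c & uprime)
    return hit <= 1


def separator_is_legal(elig: ELIG, u: Iterable) -> bool:
    """Legal separator: for every input tree ``T``, the members from
    ``LG(T)`` form a clique there (pairwise incident edges of a tree share
    a common endpoint)."""
    us = frozenset(u)
    for e in us:
        if e not in elig.graph:
            raise DomainError(f"{e} is not an ELIG vertex")
    for i in range(len(elig.display.profile.trees)):
        members = sorted(us & elig.tree_members(i))
        for e1, e2 in itertools.combinations(members, 2):
            if not set(e1) & set(e2):
                return False
    return True


# ---------------------------------------------------------------------------
# Cuts -> splits


def cut_to_split(display: DisplayGraph, f: Cut | Iterable[Edge]) -> Split:
    """``sigma(F)``: the label bipartition induced by the two components of
    ``G(P) - F``.  Defined (and guaranteed non-empty on both sides) for nice
    minimal cuts."""
    edges = f.edges if isinstance(f, Cut) else frozenset(edge_key(*e) for e in f)
    if not is_minimal_cut(display.graph, edges):
        raise DomainError("sigma(F) requires a minimal cut")
    legal, nice = classify_cut(display, edges)
    if not nice:
        raise DomainError("sigma(F) requires a nice cut")
    comps = _components_after(display.graph, edges)
    a = {v for v in comps[0] if display.is_leaf(v)}
    b = {v for v in comps[1] if display.is_leaf(v)}
    return Split(a, b)
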