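"""Agreement supertrees (ASTs) via restricted cut sets, plus the cut
function and edge-splitting machinery used to reason about them.

A supertree *agrees* with an input tree when restriction gives back exactly
that tree (split-set equality, not mere containment).  A profile has an AST
exactly when the display graph has a complete set of pairwise parallel legal
minimal cuts in which every cut contains *at most one edge per input tree*.
The decider reuses the compatibility search with that extra candidate
filter; the cut function ``Psi`` and the splitting operation are shipped as
verification/normalization utilities so the supporting theory is itself
exercisable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .compat import (
    CutSet,
    Decision,
    Guard,
    _decide,
    all_legal_minimal_cuts,
    build_supertree_from_cuts,
    enumerate_binary_topologies,
)
from .errors import (
    DomainError,
    InternalConsistencyError,
    ResourceExhaustedError,
)
from .graphs import DisplayGraph, build_display_graph, _components_after
from .phylo import (
    PhyloTree,
    Profile,
    displays_and_agrees,
    edge_key,
    restrict_split_set,
    tree_splits,
)

__all__ = [
    "AgreementCertificate",
    "CutFunction",
    "find_agreement_cutset",
    "decide_agreement",
    "cut_function",
    "split_edge_at",
    "normalize_ast",
    "brute_force_ast",
]


@dataclass
class AgreementCertificate:
    """Witness of agreement: a complete parallel legal minimal cut set with
    at most one edge per input tree in each cut, and the AST it induces."""

    cutset: CutSet | None
    ast: PhyloTree
    components: list["AgreementCertificate"] = field(default_factory=list)


def find_agreement_cutset(profile: Profile, guard: Guard = Guard()) -> CutSet | None:
    """Like the compatibility search, with candidates pre-filtered to cuts
    containing at most one edge of every input tree."""
    display = build_display_graph(profile)
    if not display.is_connected():
        raise DomainError("display graph is disconnected; partition the profile")
    from .compat import _find_cutset

    return _find_cutset(display, guard, per_tree_limit=1)


def decide_agreement(profile: Profile, guard: Guard = Guard()) -> Decision:
    """Decide AST existence; on success build the AST from the cut-induced
    splits and verify split-set equality against every input."""
    inner = _decide(profile, guard, per_tree_limit=1)
    if inner.status != "yes":
        return inner
    ast = inner.certificate.supertree
    for t in profile:
        _, agrees = displays_and_agrees(ast, t)
        if not agrees:
            raise InternalConsistencyError(
                "tree built from an agreement cut set fails to agree with an input"
            )
    cert = AgreementCertificate(
        cutset=inner.certificate.cutset,
        ast=ast,
        components=[
            AgreementCertificate(cutset=c.cutset, ast=c.supertree)
            for c in inner.certificate.components
        ],
    )
    return Decision("yes", cert)


# ---------------------------------------------------------------------------
# The cut function Psi


@dataclass
class CutFunction:
    """``Psi`` maps each AST edge to the input-tree edges it serves as
    agreement edge for; every ``Psi(e)`` is a cut of the display graph.

    ``sides[e]`` holds the label bipartition ``(L_u, L_v)`` and
    ``vertex_sides[e]`` the vertex partition ``(V_u, V_v)`` of the display
    graph, both keyed on the canonical edge and ordered to match the edge
    key's endpoint order.
    """

    ast: PhyloTree
    display: DisplayGraph
    psi: dict
    sides: dict
    vertex_sides: dict

    def is_minimal(self, e) -> bool:
        """``Psi(e)`` is a minimal cut iff removal leaves
        exactly two components."""
        e = edge_key(*e)
        comps = _components_after(self.display.graph, self.psi[e])
        return len(comps) == 2


def _label_sides(ast: PhyloTree, e) -> tuple[frozenset, frozenset]:
    u, v = e
    g = ast.graph
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in g.neighbors(x):
            if {x, y} == {u, v} or y in seen:
                continue
            seen.add(y)
            stack.append(y)
    lu = frozenset(x for x in seen if x in ast.leaves)
    return lu, ast.leaves - lu


def cut_function(ast: PhyloTree, profile: Profile) -> CutFunction:
    """Compute ``Psi`` for an AST of the profile (domain error otherwise)."""
    if ast.labels != profile.label_universe:
        raise DomainError(
            "an agreement supertree must carry exactly the profile's labels"
        )
    for t in profile:
        _, agrees = displays_and_agrees(ast, t)
        if not agrees:
            raise DomainError("tree does not agree with every input")
    display = build_display_graph(profile)
    tree_edge_splits = []
    for t in profile:
        per_edge = {}
        for a, b in t.graph.edges():
            e = edge_key(a, b)
            la, lb = _label_sides(t, e)
            per_edge[e] = (la, lb)
        tree_edge_splits.append(per_edge)

    psi: dict = {}
    sides: dict = {}
    vertex_sides: dict = {}
    for a, b in ast.graph.edges():
        e = edge_key(a, b)
        lu, lv = _label_sides(ast, e)
        sides[e] = (lu, lv)
        members = set()
        for per_edge in tree_edge_splits:
            for f, (fa, fb) in per_edge.items():
                if (fa <= lu and fb <= lv) or (fa <= lv and fb <= lu):
                    members.add(f)
        psi[e] = frozenset(members)
        vertex_sides[e] = (
            _steiner_vertices(profile, lu),
            _steiner_vertices(profile, lv),
        )
    return CutFunction(ast, display, psi, sides, vertex_sides)


def _steiner_vertices(profile: Profile, labels: frozenset) -> frozenset:
    """``V_x``: union over trees of the vertices of the minimal subtree
    connecting the tree's labels on side ``x``."""
    out: set = set()
    for t in profile:
        want = t.labels & labels
        if not want:
            continue
        if len(want) == 1:
            out |= want
            continue
        g = t.graph.copy()
        peel = [v for v in g if g.degree(v) <= 1 and v not in want]
        while peel:
            v = peel.pop()
            if v not in g:
                continue
            nbrs = list(g.neighbors(v))
            g.remove_node(v)
            for u in nbrs:
                if g.degree(u) <= 1 and u not in want:
                    peel.append(u)
        out |= set(g.nodes)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Splitting an edge (the Psi-minimality normalization pipeline)


def split_edge_at(ast: PhyloTree, e, u, profile: Profile) -> PhyloTree:
    """Split edge ``e = {u, v}`` at ``u``: delete the ``v``-side subtree and
    re-attach, per connected component of ``G(P) - Psi(e)`` meeting ``L_v``,
    the minimal subtree for that component's labels directly to ``u``.

    Defined when ``Psi(e)`` is not minimal and the component partition of
    ``L_v`` has more than one part; preserves agreement with every input.
    """
    e = edge_key(*e)
    if u not in e:
        raise DomainError(f"{u!r} is not an endpoint of {e}")
    v = e[1] if e[0] == u else e[0]
    cf = cut_function(ast, profile)
    if cf.is_minimal(e):
        raise DomainError("Psi(e) is already a minimal cut; nothing to split")
    lu, lv = cf.sides[e]  # ordered to match (e[0], e[1])
    l_v = lv if e[0] == u else lu
    parts = _partition_by_components(cf.display, cf.psi[e], l_v)
    if len(parts) <= 1:
        raise DomainError(
            "the far-side label partition has a single part; split at the "
            "other endpoint"
        )
    g = ast.graph.copy()
    # v-side vertices
    side = _side_vertices(ast, e, v)
    subtrees = [_rooted_component_subtree(ast, side, v, part) for part in parts]
    g.remove_nodes_from(side)
    attach = u
    if u in ast.leaves:
        # a labelled attachment point would become internal; interpose a new
        # unlabelled vertex so the result stays a phylogenetic tree
        attach = "sp.0"
        while attach in g:
            attach = attach + "x"
        g.add_edge(u, attach)
    for sub_g, root in subtrees:
        g = nx.union(g, sub_g)
        g.add_edge(attach, root)
    return PhyloTree(g, ast.leaves)


def _partition_by_components(display: DisplayGraph, cut_edges, labels) -> list[frozenset]:
    comps = _components_after(display.graph, frozenset(cut_edges))
    parts = []
    for c in comps:
        part = frozenset(x for x in c if x in labels)
        if part:
            parts.append(part)
    return sorted(parts, key=sorted)


def _side_vertices(ast: PhyloTree, e, v) -> set:
    g = ast.graph
    u = e[1] if e[0] == v else e[0]
    seen = {v}
    stack = [v]
    while stack:
        x = stack.pop()
        for y in g.neighbors(x):
            if {x, y} == {u, v} or y in seen:
                continue
            seen.add(y)
            stack.append(y)
    return seen


def _rooted_component_subtree(ast: PhyloTree, side: set, v, labels: frozenset):
    """Minimal subtree of the ``v``-side connecting ``labels``, rooted at
    the vertex closest to ``v``, with every *other* degree-two vertex
    suppressed.  Returns ``(graph, root)`` with fresh internal vertex ids
    left as-is (they are unique within the AST)."""
    g = ast.graph.subgraph(side).copy()
    if len(labels) == 1:
        (leaf,) = labels
        h = nx.Graph()
        h.add_node(leaf)
        return h, leaf
    peel = [x for x in g if g.degree(x) <= 1 and x not in labels]
    while peel:
        x = peel.pop()
        if x not in g:
            continue
        nbrs = list(g.neighbors(x))
        g.remove_node(x)
        for y in nbrs:
            if g.degree(y) <= 1 and y not in labels:
                peel.append(y)
    # root: the subtree vertex nearest to v in the original v-side subtree
    dist = nx.single_source_shortest_path_length(ast.graph.subgraph(side), v)
    root = min(g.nodes, key=lambda x: (dist[x], str(x)))
    changed = True
    while changed:
        changed = False
        for x in list(g.nodes):
            if x == root or x in labels:
                continue
            if g.degree(x) == 2:
                a, b = g.neighbors(x)
                g.remove_node(x)
                g.add_edge(a, b)
                changed = True
    return g, root


def normalize_ast(ast: PhyloTree, profile: Profile, max_rounds: int = 10_000) -> PhyloTree:
    """Repeatedly split edges with non-minimal ``Psi`` (largest ``|Psi|``
    first) until every ``Psi(e)`` is a minimal cut; termination is bounded
    by the potential argument behind the splitting operation."""
    current = ast
    for _ in range(max_rounds):
        cf = cut_function(current, profile)
        bad = [e for e in cf.psi if not cf.is_minimal(e)]
        if not bad:
            return current
        e_star = max(bad, key=lambda e: (len(cf.psi[e]), str(e)))
        u, v = e_star
        lu, lv = cf.sides[e_star]
        m_v = len(_partition_by_components(cf.display, cf.psi[e_star], lv))
        m_u = len(_partition_by_components(cf.display, cf.psi[e_star], lu))
        if m_v > 1:
            current = split_edge_at(current, e_star, u, profile)
        elif m_u > 1:
            current = split_edge_at(current, e_star, v, profile)
        else:  # pragma: no cover - contradicts non-minimality
            raise InternalConsistencyError(
                "non-minimal Psi(e) with single-part partitions on both sides"
            )
    raise InternalConsistencyError("splitting loop failed to terminate")


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def _all_topology_split_sets(labels) -> set[frozenset]:
    """Split sets of every phylogenetic tree on ``labels``, multifurcating
    included: all subsets of each binary topology's internal splits."""
    out: set[frozenset] = set()
    for s in enumerate_binary_topologies(labels):
        internal, _ = tree_splits(s)
        items = sorted(internal)
        for r in range(len(items) + 1):
            for combo in itertools.combinations(items, r):
                out.add(frozenset(combo))
    return out


def brute_force_ast(profile: Profile, max_labels: int = 6) -> bool:
    """Oracle: enumerate every (possibly multifurcating) supertree topology
    as a split set and test agreement by split-set restriction equality."""
    labels = profile.label_universe
    if len(labels) > max_labels:
        raise ResourceExhaustedError(
            f"{len(labels)} labels exceeds oracle guard {max_labels}"
        )
    inputs = []
    for t in profile:
        internal, _ = tree_splits(t)
        inputs.append((t.labels, internal))
    for cand in _all_topology_split_sets(labels):
        ok = True
        for tl, t_splits in inputs:
            if restrict_split_set(cand, tl) != t_splits:
                ok = False
                break
        if ok:
            return True
    return False
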