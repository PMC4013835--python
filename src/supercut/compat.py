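"""Deciding supertree compatibility via complete sets of parallel cuts.

A profile of unrooted trees is compatible -- some supertree displays every
input -- exactly when the display graph admits a *complete* set of pairwise
parallel legal minimal cuts: one in which every internal edge ``e`` of every
input tree ``T`` appears as the sole edge of ``T`` in some member cut.  The
decider below realizes that existential characterization as an exact
backtracking search over per-edge candidate cuts; a found set is minimized
(after which all members are nice) and converted into a supertree through
the cut-induced splits ``sigma(F)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import (
    DomainError,
    InternalConsistencyError,
    ResourceExhaustedError,
)
from .graphs import (
    Cut,
    CutSet,
    DisplayGraph,
    build_display_graph,
    classify_cut,
    cut_to_split,
    cuts_parallel,
    enumerate_minimal_cuts,
)
from .phylo import (
    PhyloTree,
    Profile,
    Split,
    displays_and_agrees,
    edge_key,
    restrict_split_set,
    tree_from_splits,
    tree_splits,
)

__all__ = [
    "Guard",
    "CompatibilityCertificate",
    "Decision",
    "all_legal_minimal_cuts",
    "candidate_cuts_for_edge",
    "cutset_is_complete",
    "find_complete_parallel_cutset",
    "minimize_cutset",
    "build_supertree_from_cuts",
    "decide_compatibility",
    "brute_force_compatible",
    "enumerate_binary_topologies",
]


@dataclass(frozen=True)
class Guard:
    """Resource limits for the exact searches.

    ``max_vertices`` bounds the display graph handed to exhaustive cut
    enumeration; ``max_checks`` bounds the number of pairwise-parallelism
    evaluations performed by the backtracking search.
    """

    max_vertices: int = 18
    max_checks: int = 5_000_000


@dataclass
class CompatibilityCertificate:
    """A verifiable witness of compatibility."""

    cutset: CutSet | None
    splits: set[Split]
    supertree: PhyloTree
    components: list["CompatibilityCertificate"] = field(default_factory=list)


@dataclass
class Decision:
    """Outcome of a decider: ``status`` is ``"yes"``, ``"no"`` or
    ``"unknown"`` (guard exhausted before the search completed)."""

    status: str
    certificate: object | None = None

    @property
    def answer(self) -> bool | None:
        return {"yes": True, "no": False}.get(self.status)


# ---------------------------------------------------------------------------
# Candidate cuts


def all_legal_minimal_cuts(display: DisplayGraph, guard: Guard = Guard()) -> list[Cut]:
    """Exhaustive legal minimal cuts of a connected display graph."""
    cuts = enumerate_minimal_cuts(display.graph, guard.max_vertices)
    out = []
    for c in cuts:
        c.legal, c.nice = classify_cut(display, c)
        if c.legal:
            out.append(c)
    return out


def _owner_tree(display: DisplayGraph, e) -> int:
    e = edge_key(*e)
    owners = display.provenance.get(e)
    if not owners:
        raise DomainError(f"edge {e} not in display graph")
    return min(owners)


def candidate_cuts_for_edge(display: DisplayGraph, e, all_cuts: Iterable[Cut]) -> list[Cut]:
    """Legal minimal cuts ``F`` whose slice in ``e``'s tree is exactly
    ``{e}`` -- the cuts that can cover ``e`` in a complete set."""
    e = edge_key(*e)
    if not display.is_internal_edge(e):
        raise DomainError(f"{e} is not an internal edge")
    ti = _owner_tree(display, e)
    return [c for c in all_cuts if display.tree_slice(c.edges, ti) == {e}]


def _internal_tree_edges(display: DisplayGraph) -> list:
    out = []
    for t in display.profile:
        out.extend(t.internal_edges())
    return sorted(out)


def cutset_is_complete(display: DisplayGraph, cuts: Iterable) -> bool:
    """Complete: every internal edge of every input tree is the sole edge of
    its tree in some member cut."""
    edge_sets = [c.edges if isinstance(c, Cut) else frozenset(c) for c in cuts]
    for e in _internal_tree_edges(display):
        ti = _owner_tree(display, e)
        if not any(display.tree_slice(f, ti) == {e} for f in edge_sets):
            return False
    return True


# ---------------------------------------------------------------------------
# The backtracking search


class _ParallelOracle:
    """Memoized pairwise-parallelism with a work budget."""

    def __init__(self, graph: nx.Graph, guard: Guard):
        self.graph = graph
        self.guard = guard
        self.cache: dict[frozenset, bool] = {}
        self.checks = 0

    def __call__(self, c1: Cut, c2: Cut) -> bool:
        if c1.edges == c2.edges:
            return True
        key = frozenset((c1.edges, c2.edges))
        if key not in self.cache:
            self.checks += 1
            if self.checks > self.guard.max_checks:
                raise ResourceExhaustedError(
                    f"parallelism budget of {self.guard.max_checks} checks exhausted"
                )
            self.cache[key] = cuts_parallel(self.graph, c1, c2)
        return self.cache[key]


def _search_cutset(
    display: DisplayGraph,
    candidates: dict,
    guard: Guard,
) -> list[Cut] | None:
    """Exact backtracking: cover every internal tree edge by one candidate
    cut, most-constrained edge first, pruning on pairwise parallelism."""
    par = _ParallelOracle(display.graph, guard)
    covers: dict[frozenset, set] = {}
    for e, cands in candidates.items():
        for c in cands:
            covers.setdefault(c.edges, set()).add(e)

    def rec(uncovered: frozenset, chosen: list[Cut]):
        if not uncovered:
            return list(chosen)
        e = min(uncovered, key=lambda x: (len(candidates[x]), str(x)))
        for cand in candidates[e]:
            if any(c.edges == cand.edges for c in chosen):
                continue  # already chosen yet e uncovered: impossible; skip
            if not all(par(cand, c) for c in chosen):
                continue
            chosen.append(cand)
            res = rec(uncovered - covers[cand.edges], chosen)
            if res is not None:
                return res
            chosen.pop()
        return None

    all_edges = frozenset(candidates)
    return rec(all_edges, [])


def find_complete_parallel_cutset(
    profile: Profile, guard: Guard = Guard()
) -> CutSet | None:
    """A complete set of pairwise parallel legal minimal cuts of ``G(P)``,
    minimized so that no proper subset is complete, or ``None`` when an
    exhaustive search finds none.

    Requires a connected display graph (callers partition otherwise).
    """
    display = build_display_graph(profile)
    if not display.is_connected():
        raise DomainError("display graph is disconnected; partition the profile")
    return _find_cutset(display, guard, per_tree_limit=None)


def _find_cutset(display: DisplayGraph, guard: Guard, per_tree_limit: int | None):
    pool = all_legal_minimal_cuts(display, guard)
    if per_tree_limit is not None:
        k = len(display.profile.trees)
        pool = [
            c
            for c in pool
            if all(
                len(display.tree_slice(c.edges, i)) <= per_tree_limit
                for i in range(k)
            )
        ]
    candidates = {}
    for e in _internal_tree_edges(display):
        cands = candidate_cuts_for_edge(display, e, pool)
        if not cands:
            return None
        candidates[e] = cands
    found = _search_cutset(display, candidates, guard)
    if found is None:
        return None
    minimized = minimize_cutset(display, found)
    for c in minimized:
        legal, nice = classify_cut(display, c)
        c.legal, c.nice = legal, nice
        if not nice:  # a minimal complete subset must consist of nice cuts
            raise InternalConsistencyError(
                f"minimized cut {c!r} is not nice; search is buggy"
            )
    return CutSet.canonical(minimized)


def minimize_cutset(display: DisplayGraph, cuts: Iterable[Cut]) -> list[Cut]:
    """Greedily drop cuts (in canonical order) while completeness holds; the
    result has no complete proper subset."""
    current = sorted(set(cuts), key=Cut.sort_key)
    if not cutset_is_complete(display, current):
        raise DomainError("cut set is not complete")
    for c in list(current):
        trial = [x for x in current if x.edges != c.edges]
        if cutset_is_complete(display, trial):
            current = trial
    return current


# ---------------------------------------------------------------------------
# Supertree construction (splits-equivalence route)


def build_supertree_from_cuts(profile: Profile, cutset: CutSet) -> PhyloTree:
    """``Sigma(F)`` (non-trivial splits of the member cuts) plus all trivial
    splits determines the supertree; the result is checked to display every
    input before being returned."""
    display = build_display_graph(profile)
    splits = set()
    for c in cutset:
        s = cut_to_split(display, c)
        if not s.is_trivial:
            splits.add(s)
    tree = tree_from_splits(splits, profile.label_universe)
    for t in profile:
        disp, _ = displays_and_agrees(tree, t)
        if not disp:
            raise InternalConsistencyError(
                "supertree built from a valid cut set fails to display an input"
            )
    return tree


# ---------------------------------------------------------------------------
# Decider


def decide_compatibility(profile: Profile, guard: Guard = Guard()) -> Decision:
    """Decide compatibility; on success the certificate carries the cut set,
    the induced splits and a compatible supertree.

    A disconnected display graph partitions the profile into sub-profiles
    decided independently; their supertrees are chained by subdividing one
    edge of each and connecting the subdividers, which leaves every input's
    restriction unchanged.
    """
    return _decide(profile, guard, per_tree_limit=None)


def _decide(profile: Profile, guard: Guard, per_tree_limit: int | None) -> Decision:
    display = build_display_graph(profile)
    comps = display.components()
    if len(comps) > 1:
        sub_decisions = []
        counter = itertools.count()
        for comp in sorted(comps, key=lambda c: min(map(str, c))):
            sub = Profile(
                [t for t in profile if set(t.graph.nodes) <= comp]
            )
            d = _decide(sub, guard, per_tree_limit)
            if d.status != "yes":
                return Decision(d.status)
            sub_decisions.append(d)
        supertree = _chain_supertrees(
            [d.certificate.supertree for d in sub_decisions], counter
        )
        cert = CompatibilityCertificate(
            cutset=None,
            splits=set().union(*(d.certificate.splits for d in sub_decisions)),
            supertree=supertree,
            components=[d.certificate for d in sub_decisions],
        )
        return Decision("yes", cert)

    try:
        cutset = _find_cutset(display, guard, per_tree_limit)
    except ResourceExhaustedError:
        return Decision("unknown")
    if cutset is None:
        return Decision("no")
    supertree = build_supertree_from_cuts(profile, cutset)
    splits = {cut_to_split(display, c) for c in cutset}
    return Decision(
        "yes",
        CompatibilityCertificate(
            cutset=cutset,
            splits={s for s in splits if not s.is_trivial},
            supertree=supertree,
        ),
    )


def _chain_supertrees(trees: list[PhyloTree], counter) -> PhyloTree:
    # internal ids may collide across component supertrees; re-namespace
    relabeled = []
    for i, t in enumerate(trees):
        mapping = {
            v: f"c{i}.{j}"
            for j, v in enumerate(sorted(t.internal_vertices(), key=str))
        }
        relabeled.append(PhyloTree(nx.relabel_nodes(t.graph, mapping), t.leaves))
    trees = relabeled
    combined = trees[0]
    for t in trees[1:]:
        g = nx.union(combined.graph, t.graph)
        pa = _attach_point(combined, g, counter)
        pb = _attach_point(t, g, counter)
        g.add_edge(pa, pb)
        combined = PhyloTree(g, combined.leaves | t.leaves)
    return combined


def _attach_point(tree: PhyloTree, g: nx.Graph, counter):
    if tree.graph.number_of_edges() == 0:
        return next(iter(tree.graph.nodes))
    u, v = min((edge_key(u, v) for u, v in tree.graph.edges()), key=str)
    w = f"j.{next(counter)}"
    g.remove_edge(u, v)
    g.add_edge(u, w)
    g.add_edge(w, v)
    return w


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def enumerate_binary_topologies(labels: Iterable[str]):
    """All unrooted binary topologies on a label set ((2n-5)!! of them),
    yielded as PhyloTree objects.  Intended for small n."""
    labels = sorted(set(labels))
    n = len(labels)
    g = nx.Graph()
    if n == 0:
        return
    if n == 1:
        g.add_node(labels[0])
        yield PhyloTree(g, labels)
        return
    if n == 2:
        g.add_edge(labels[0], labels[1])
        yield PhyloTree(g, labels)
        return
    base = nx.Graph()
    base.add_edges_from(("b.0", x) for x in labels[:3])

    def grow(g: nx.Graph, i: int):
        if i == n:
            yield PhyloTree(g.copy(), labels, validate=False)
            return
        label = labels[i]
        for u, v in sorted((edge_key(a, b) for a, b in g.edges()), key=str):
            w = f"b.{i}"
            g.remove_edge(u, v)
            g.add_edge(u, w)
            g.add_edge(w, v)
            g.add_edge(w, label)
            yield from grow(g, i + 1)
            g.remove_node(w)
            g.add_edge(u, v)

    yield from grow(base, 3)


def brute_force_compatible(profile: Profile, max_labels: int = 7) -> bool:
    """Oracle: enumerate every binary supertree topology and test display.

    A compatible supertree exists iff a binary one does (displaying is
    closed under refinement).  Display is tested on split sets via
    restriction -- a route independent of the cut machinery.
    """
    labels = profile.label_universe
    if len(labels) > max_labels:
        raise ResourceExhaustedError(
            f"{len(labels)} labels exceeds oracle guard {max_labels}"
        )
    inputs = []
    for t in profile:
        internal, _ = tree_splits(t)
        inputs.append((t.labels, internal))
    for s in enumerate_binary_topologies(labels):
        s_internal, _ = tree_splits(s)
        ok = True
        for tl, t_splits in inputs:
            if not t_splits <= restrict_split_set(s_internal, tl):
                ok = False
                break
        if ok:
            return True
    return False
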