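"""Unrooted phylogenetic trees, Newick I/O, restriction, and splits.

A phylogenetic tree is an unrooted, acyclic, connected graph whose degree-one
vertices (leaves) are bijectively labelled and which contains no degree-two
vertices.  Trees on one label (a single labelled vertex) and on two labels
(a single edge) are permitted degenerate forms.  Every edge ``e`` of a tree
``T`` induces a bipartition of the label set -- the split ``sigma_e(T)``;
the splits of internal edges, ``Sigma(T)``, are the currency in which
compatibility and agreement of trees are expressed.

Leaf vertices are represented by their label strings; internal vertices are
opaque strings namespaced per tree (``"t<i>.<n>"``) so that distinct trees in
a profile never share internal vertex ids.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
import networkx as nx

from .errors import (
    DomainError,
    IncompatibleSplitsError,
    NewickParseError,
    ValidationError,
)

__all__ = [
    "Split",
    "PhyloTree",
    "Profile",
    "parse_newick",
    "write_newick",
    "restrict_tree",
    "tree_splits",
    "splits_compatible",
    "split_set_compatible",
    "tree_from_splits",
    "restrict_split_set",
    "displays_and_agrees",
    "read_profile",
    "write_profile",
]


# ---------------------------------------------------------------------------
# Splits


class Split:
    """An unordered bipartition ``A|B`` of a label set into non-empty sides.

    ``Split({'a','b'}, {'c','d'})`` equals ``Split({'c','d'}, {'a','b'})``.
    A split is *trivial* when one side is a singleton.  The canonical form
    (used for hashing, ordering and printing) puts the lexicographically
    smaller side first, comparing sides by their sorted member lists.
    """

    __slots__ = ("side_a", "side_b", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise DomainError("split sides must be non-empty")
        if a & b:
            raise DomainError(f"split sides overlap: {sorted(a & b)}")
        ka, kb = sorted(a), sorted(b)
        if kb < ka:
            a, b, ka, kb = b, a, kb, ka
        self.side_a = a
        self.side_b = b
        self._key = (tuple(ka), tuple(kb))

    @property
    def labels(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def side_of(self, label: str) -> frozenset[str]:
        if label in self.side_a:
            return self.side_a
        if label in self.side_b:
            return self.side_b
        raise DomainError(f"label {label!r} not in split universe")

    def __eq__(self, other) -> bool:
        return isinstance(other, Split) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __lt__(self, other: "Split") -> bool:
        return self._key < other._key

    def __repr__(self) -> str:
        return "{}|{}".format("".join(self._key[0]), "".join(self._key[1]))


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Two splits ``A1|A2`` and ``B1|B2`` over one label universe are
    compatible iff at least one of the four side intersections is empty."""
    return (
        not (s1.side_a & s2.side_a)
        or not (s1.side_a & s2.side_b)
        or not (s1.side_b & s2.side_a)
        or not (s1.side_b & s2.side_b)
    )


def split_set_compatible(splits: Iterable[Split]) -> tuple[Split, Split] | None:
    """Return an incompatible pair, or ``None`` if all pairs are compatible."""
    items = sorted(set(splits))
    for s1, s2 in itertools.combinations(items, 2):
        if not splits_compatible(s1, s2):
            return (s1, s2)
    return None


def restrict_split_set(splits: Iterable[Split], labels: Iterable[str]) -> set[Split]:
    """Non-trivial restrictions ``(A∩Y)|(B∩Y)`` of a split set to ``Y``.

    For a tree ``S`` this maps ``Sigma(S)`` onto ``Sigma(S|Y)``; it is the
    split-level counterpart of :func:`restrict_tree` and is used as the
    independent route in the brute-force oracles.
    """
    y = frozenset(labels)
    out: set[Split] = set()
    for s in splits:
        a, b = s.side_a & y, s.side_b & y
        if len(a) >= 2 and len(b) >= 2:
            out.add(Split(a, b))
    return out


# ---------------------------------------------------------------------------
# Trees


class PhyloTree:
    """An unrooted leaf-labelled tree backed by a :class:`networkx.Graph`.

    Leaf vertices are their label strings; internal vertices are any other
    (string) ids.  The constructor validates the tree invariants.
    """

    __slots__ = ("graph", "leaves")

    def __init__(self, graph: nx.Graph, leaves: Iterable[str], validate: bool = True):
        self.graph = graph
        self.leaves = frozenset(leaves)
        if validate:
            self._validate()

    def _validate(self) -> None:
        g = self.graph
        n = g.number_of_nodes()
        if n == 0:
            raise ValidationError("empty tree")
        if not nx.is_connected(g):
            raise ValidationError("tree graph is not connected")
        if g.number_of_edges() != n - 1:
            raise ValidationError("tree graph contains a cycle")
        for v in g:
            deg = g.degree(v)
            if v in self.leaves:
                if deg > 1:
                    raise ValidationError(f"labelled vertex {v!r} has degree {deg}")
            else:
                if deg <= 2:
                    raise ValidationError(
                        f"internal vertex {v!r} has degree {deg} (< 3)"
                    )
        if self.leaves != {v for v in g if v in self.leaves}:
            raise ValidationError("leaf set does not match graph vertices")
        if not self.leaves:
            raise ValidationError("tree has no labelled vertices")

    # -- convenience ------------------------------------------------------

    @property
    def labels(self) -> frozenset[str]:
        return self.leaves

    def is_leaf(self, v) -> bool:
        return v in self.leaves

    def internal_vertices(self) -> list:
        return [v for v in self.graph if v not in self.leaves]

    def edges(self) -> list[tuple]:
        return [edge_key(u, v) for u, v in self.graph.edges()]

    def internal_edges(self) -> list[tuple]:
        return [
            edge_key(u, v)
            for u, v in self.graph.edges()
            if u not in self.leaves and v not in self.leaves
        ]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.graph.copy(), self.leaves, validate=False)

    def __repr__(self) -> str:
        return f"PhyloTree({write_newick(self)!r})"


def edge_key(u, v) -> tuple:
    """Canonical unordered representation of an edge (sorted by str)."""
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class Profile:
    """An ordered collection of input trees over a shared label universe.

    Internal vertex-id spaces of distinct trees must be disjoint (guaranteed
    when trees come from :func:`parse_newick` with distinct indices).
    """

    trees: list[PhyloTree] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, int] = {}
        for i, t in enumerate(self.trees):
            for v in t.internal_vertices():
                if v in seen:
                    raise ValidationError(
                        f"internal vertex id {v!r} shared by trees "
                        f"{seen[v]} and {i}"
                    )
                seen[v] = i

    @property
    def label_universe(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for t in self.trees:
            out |= t.labels
        return out

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, tree_index: int = 0) -> PhyloTree:
    """Parse a single Newick statement into an unrooted :class:`PhyloTree`.

    Branch lengths and internal node labels are parsed and discarded; only
    topology and leaf labels are semantic.  A degree-two vertex arising from
    a rooted representation is suppressed.  Internal vertex ids are
    namespaced as ``"t<tree_index>.<n>"``.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError(
            f"Newick statement must end in ';' (offset {len(text)}): {text!r}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    g = nx.Graph()
    leaves: set[str] = set()
    counter = itertools.count(1)
    ids: dict = {}

    def vid(node):
        if node not in ids:
            if node.is_leaf():
                if node.taxon is None or node.taxon.label is None:
                    raise NewickParseError("leaf without a label")
                label = str(node.taxon.label)
                if label in leaves:
                    raise ValidationError(f"duplicate leaf label {label!r}")
                leaves.add(label)
                ids[node] = label
            else:
                ids[node] = f"t{tree_index}.{next(counter)}"
        return ids[node]

    root = dtree.seed_node
    if root.is_leaf() and not root.child_nodes():
        # single-leaf degenerate form, e.g. "a;"
        g.add_node(vid(root))
        return PhyloTree(g, leaves)
    for node in dtree.preorder_node_iter():
        u = vid(node)
        g.add_node(u)
        for child in node.child_nodes():
            g.add_edge(u, vid(child))
    _suppress_degree_two(g, leaves)
    return PhyloTree(g, leaves)


def _suppress_degree_two(g: nx.Graph, leaves: set[str]) -> None:
    """Splice out every unlabelled degree-two vertex (in place)."""
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v in leaves:
                continue
            if g.degree(v) == 2:
                a, b = g.neighbors(v)
                g.remove_node(v)
                g.add_edge(a, b)
                changed = True
            elif g.degree(v) == 0 and g.number_of_nodes() > 1:
                g.remove_node(v)
                changed = True


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree deterministically.

    Children are listed in lexicographic order of their smallest descendant
    label, so equal trees produce byte-identical output and
    ``parse_newick(write_newick(t))`` has the same split set as ``t``.
    """
    g = tree.graph
    if g.number_of_nodes() == 1:
        return f"{next(iter(tree.leaves))};"
    if g.number_of_nodes() == 2:
        a, b = sorted(tree.leaves)
        return f"({a},{b});"
    # root at the internal vertex adjacent to the smallest label
    first = min(tree.leaves)
    root = next(iter(g.neighbors(first)))

    def emit(v, parent) -> tuple[str, str]:
        # returns (newick, smallest descendant label)
        if tree.is_leaf(v):
            return v, v
        parts = [emit(u, v) for u in g.neighbors(v) if u != parent]
        parts.sort(key=lambda p: p[1])
        return "(" + ",".join(p[0] for p in parts) + ")", min(p[1] for p in parts)

    body, _ = emit(root, None)
    return body + ";"


def read_profile(stream, name_prefix_start: int = 0) -> Profile:
    """Read a profile: one Newick statement per line, ``#`` comments ignored."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    trees = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trees.append(parse_newick(line, tree_index=name_prefix_start + len(trees)))
    return Profile(trees)


def write_profile(profile: Profile) -> str:
    return "".join(write_newick(t) + "\n" for t in profile)


# ---------------------------------------------------------------------------
# Restriction and splits


def restrict_tree(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    """The restriction ``T|Y``: minimal subtree connecting ``Y`` with all
    degree-two vertices suppressed."""
    y = frozenset(labels)
    if not y:
        raise DomainError("restriction label set is empty")
    if not y <= tree.labels:
        raise DomainError(f"labels not in tree: {sorted(y - tree.labels)}")
    g = tree.graph.copy()
    # peel leaves (in the graph sense) that are not wanted labels
    peel = [v for v in g if g.degree(v) <= 1 and v not in y]
    while peel:
        v = peel.pop()
        if v not in g:
            continue
        nbrs = list(g.neighbors(v))
        g.remove_node(v)
        for u in nbrs:
            if g.degree(u) <= 1 and u not in y:
                peel.append(u)
    _suppress_degree_two(g, set(y))
    return PhyloTree(g, y)


def tree_splits(tree: PhyloTree) -> tuple[set[Split], set[Split]]:
    """Per-edge splits, partitioned into internal-edge splits ``Sigma(T)``
    and leaf-edge (trivial) splits ``Sigma_triv(T)``."""
    g = tree.graph
    internal: set[Split] = set()
    trivial: set[Split] = set()
    for u, v in g.edges():
        side = _component_labels(g, v, without_edge=(u, v), leaves=tree.leaves)
        other = tree.leaves - side
        s = Split(side, other)
        if u in tree.leaves or v in tree.leaves:
            trivial.add(s)
        else:
            internal.add(s)
    return internal, trivial


def _component_labels(g: nx.Graph, start, without_edge, leaves) -> set[str]:
    u, v = without_edge
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in g.neighbors(x):
            if {x, y} == {u, v}:
                continue
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return {x for x in seen if x in leaves}


def tree_from_splits(splits: Iterable[Split], labels: Iterable[str]) -> PhyloTree:
    """Build the unique tree displaying exactly the given non-trivial splits
    (tree popping: iterative refinement from a star).

    All trivial splits are implicitly included.  Raises
    :class:`IncompatibleSplitsError` naming an offending pair when the
    splits are not pairwise compatible; by the splits-equivalence theorem
    the processing order cannot affect the result.
    """
    universe = frozenset(labels)
    if not universe:
        raise DomainError("empty label universe")
    wanted = sorted({s for s in splits if not s.is_trivial})
    for s in wanted:
        if s.labels != universe:
            raise DomainError(f"split {s} does not bipartition the label universe")
    bad = split_set_compatible(wanted)
    if bad is not None:
        raise IncompatibleSplitsError(*bad)

    g = nx.Graph()
    if len(universe) == 1:
        g.add_node(next(iter(universe)))
        return PhyloTree(g, universe)
    if len(universe) == 2:
        a, b = sorted(universe)
        g.add_edge(a, b)
        return PhyloTree(g, universe)
    center = "s.0"
    counter = itertools.count(1)
    for x in sorted(universe):
        g.add_edge(center, x)
    for s in wanted:
        _pop_split(g, universe, s, counter)
    return PhyloTree(g, universe)


def _pop_split(g: nx.Graph, leaves: frozenset[str], s: Split, counter) -> None:
    for v in list(g.nodes):
        if v in leaves:
            continue
        branches = []
        pure = True
        for u in g.neighbors(v):
            lab = _component_labels(g, u, without_edge=(v, u), leaves=leaves)
            if lab <= s.side_a:
                branches.append((u, "a"))
            elif lab <= s.side_b:
                branches.append((u, "b"))
            else:
                pure = False
                break
        if not pure:
            continue
        a_br = [u for u, side in branches if side == "a"]
        b_br = [u for u, side in branches if side == "b"]
        if not a_br or not b_br:
            continue
        if len(a_br) == 1 or len(b_br) == 1:
            return  # split already realized by an existing edge at v
        w = f"s.{next(counter)}"
        for u in a_br:
            g.remove_edge(v, u)
            g.add_edge(w, u)
        g.add_edge(v, w)
        return
    raise IncompatibleSplitsError(s, s)  # unreachable for compatible inputs


def displays_and_agrees(supertree: PhyloTree, t: PhyloTree) -> tuple[bool, bool]:
    """``displays`` iff ``Sigma(t) ⊆ Sigma(S|L(t))``; ``agrees`` iff the two
    split sets are equal.  Agreement implies display."""
    if not t.labels <= supertree.labels:
        raise DomainError("input tree labels not contained in supertree labels")
    restricted = restrict_tree(supertree, t.labels)
    sup_splits, _ = tree_splits(restricted)
    t_internal, _ = tree_splits(t)
    displays = t_internal <= sup_splits
    agrees = t_internal == sup_splits
    return displays, agrees
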