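"""Independent certificate verification.

Re-checks cut-set certificates directly from the definitions (component
counting, literal minimality, completeness by enumeration) in a code path
separate from the construction-side predicates, so that a bug in the search
cannot vouch for its own output.  Returns a list of human-readable
problems; an empty list means the certificate is valid.
"""

from __future__ import annotations

import itertools
import json

import networkx as nx

from .errors import DomainError
from .phylo import Profile, displays_and_agrees, edge_key

__all__ = [
    "verify_cutset_certificate",
    "cuts_to_json",
    "cuts_from_json",
]


def _display_graph_raw(profile: Profile):
    """Display graph rebuilt here from first principles."""
    g = nx.Graph()
    owners: dict = {}
    for i, t in enumerate(profile):
        for v in t.graph.nodes:
            g.add_node(v)
        for u, v in t.graph.edges():
            g.add_edge(u, v)
            owners.setdefault(edge_key(u, v), set()).add(i)
    return g, owners


def verify_cutset_certificate(
    profile: Profile,
    cuts: list[frozenset],
    agreement: bool = False,
) -> list[str]:
    """Definitional re-check of a complete pairwise-parallel legal minimal
    cut set (with the per-tree one-edge restriction when ``agreement``)."""
    problems: list[str] = []
    g, owners = _display_graph_raw(profile)
    leaves = profile.label_universe
    cuts = [frozenset(edge_key(*e) for e in f) for f in cuts]

    for idx, f in enumerate(cuts):
        name = f"cut {idx}"
        missing = [e for e in f if not g.has_edge(*e)]
        if missing:
            problems.append(f"{name}: edges not in display graph: {missing}")
            continue
        without = nx.restricted_view(g, [], f)
        comps = list(nx.connected_components(without))
        if len(comps) < 2:
            problems.append(f"{name}: removal does not disconnect")
            continue
        # literal minimality: every proper subset leaves the graph connected
        for e in sorted(f, key=str):
            sub = nx.restricted_view(g, [], f - {e})
            if not nx.is_connected(sub):
                problems.append(f"{name}: proper subset without {e} still disconnects")
                break
        for i in range(len(profile.trees)):
            slice_i = {e for e in f if i in owners[e]}
            if agreement and len(slice_i) > 1:
                problems.append(f"{name}: {len(slice_i)} edges of tree {i}")
            if len(slice_i) > 1:
                common = set.intersection(*(set(e) for e in slice_i))
                if not common:
                    problems.append(f"{name}: tree-{i} edges share no vertex")
        for c in comps:
            if not any(
                True for u in c for v in g.neighbors(u) if edge_key(u, v) not in f
            ):
                problems.append(f"{name}: a component of the remainder has no edge")
                break

    for (i1, f1), (i2, f2) in itertools.combinations(enumerate(cuts), 2):
        without = nx.restricted_view(g, [], f1)
        hit = sum(
            1
            for c in nx.connected_components(without)
            if any(u in c and v in c for u, v in f2)
        )
        if hit > 1:
            problems.append(f"cuts {i1} and {i2} are not parallel")

    for i, t in enumerate(profile):
        for u, v in t.graph.edges():
            if u in leaves or v in leaves:
                continue
            e = edge_key(u, v)
            if not any({x for x in f if i in owners[x]} == {e} for f in cuts):
                problems.append(
                    f"internal edge {e} of tree {i} is covered by no cut"
                )
    return problems


def verify_supertree(profile: Profile, supertree, agreement: bool = False) -> list[str]:
    problems = []
    if supertree.labels != profile.label_universe:
        problems.append("supertree label set differs from the profile's")
        return problems
    for i, t in enumerate(profile):
        disp, agr = displays_and_agrees(supertree, t)
        if agreement and not agr:
            problems.append(f"supertree does not agree with input tree {i}")
        elif not disp:
            problems.append(f"supertree does not display input tree {i}")
    return problems


# ---------------------------------------------------------------------------
# Certificate JSON


def cuts_to_json(cuts, meta: dict | None = None) -> str:
    payload = dict(meta or {})
    payload["cuts"] = [
        sorted([list(map(str, e)) for e in f.edges] if hasattr(f, "edges") else
               [list(map(str, e)) for e in f])
        for f in cuts
    ]
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def cuts_from_json(text: str) -> list[frozenset]:
    payload = json.loads(text)
    if "cuts" not in payload or not isinstance(payload["cuts"], list):
        raise DomainError("certificate JSON lacks a 'cuts' list")
    out = []
    for f in payload["cuts"]:
        out.append(frozenset(edge_key(u, v) for u, v in f))
    return out
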