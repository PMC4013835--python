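# Methods

## Objects and model

A phylogenetic tree here is an unrooted, connected, acyclic graph whose
degree-one vertices carry distinct labels, with no degree-two vertices;
one-leaf and two-leaf trees are allowed as degenerate forms.  Polytomies
are permitted throughout — nothing in the package assumes binary inputs.
A profile is an ordered list of such trees; internal vertex ids are
namespaced per tree (`t<i>.<n>`) so the display graph can take a plain
union of vertex sets, identifying only equal-label leaves.

Splits are unordered label bipartitions; an edge of a tree induces one, and
the internal-edge splits Σ(T) are the complete topological invariant we
use: two trees on the same labels are isomorphic iff their split sets are
equal, and S displays (agrees with) T iff Σ(T) is a subset of (equal to)
Σ(S|ℒ(T)).  All isomorphism checks in the package are split-set checks.

## Deciders

Compatibility and agreement are decided through their cut
characterizations on the display graph:

1. enumerate every minimal cut of G(P) as the boundary δ(S) of a vertex
   bipartition with both sides connected (δ(S) is a minimal cut exactly
   then);
2. keep the legal ones; for agreement, additionally drop cuts with two or
   more edges of one input tree;
3. for each internal edge *e* of each input tree, collect the candidate
   cuts whose slice in that tree is exactly {*e*};
4. exact backtracking: repeatedly take the uncovered edge with fewest
   candidates, try each candidate, prune on pairwise parallelism
   (memoized), and backtrack exhaustively;
5. minimize a found set by greedy removal in canonical order until no cut
   is redundant — a minimal complete subset provably consists of nice
   cuts, which the code asserts;
6. map each cut to its split σ(F), add trivial splits, and build the
   supertree by tree popping (iterative star refinement).  The supertree
   is checked to display — for agreement, to equal after restriction —
   every input before being returned; a failure there raises an
   internal-consistency error rather than propagating a wrong answer.

The searches are exponential by design: the enumeration is the point at
desk scale, and exhaustiveness is what makes a "no" answer meaningful.
Guards (`Guard(max_vertices=18, max_checks=5_000_000)`) bound the display
graph size for enumeration and the number of parallelism evaluations in
the backtracking; exceeding either yields the first-class outcome
`unknown`, never a silent `no`.

A disconnected display graph partitions the profile into independent
sub-profiles.  Their supertrees are combined by subdividing one edge of
each component supertree and joining the subdivision vertices; every
input's restriction is untouched, so display/agreement is preserved.  The
cut-set certificate is per-component in that case (cuts are objects of a
connected graph).

### Certificates and verification

Positive answers come with certificates (cut set, induced splits,
supertree).  `supercut.verify` re-checks them definitionally — literal
minimality (no proper subset disconnects), legality by slice intersection,
parallelism and completeness straight from the definitions — in code
deliberately separate from the construction-side predicates, so the search
cannot vouch for its own output.

### Oracles

`brute_force_compatible` enumerates all (2n−5)!! binary topologies by
sequential leaf insertion and tests display via split-set restriction; a
compatible supertree exists iff a binary one does, since displaying
survives refinement.  `brute_force_ast` enumerates multifurcating
topologies as well — every subset of a binary topology's internal splits
is realized by some tree, and every tree arises this way — and tests
split-set equality after restriction.  Both work purely on split sets,
independent of the cut machinery and of graph restriction, and both are
guarded (7 and 6 labels respectively: 945 binary topologies, and a few
hundred distinct split-set classes).

## Separators, chordality, triangulations

The edge label intersection graph LG(P) is the line graph of G(P); legal
minimal separators of LG(P) are exactly the nice minimal cuts of G(P), and
the two parallelism notions coincide — both directions are exercised as
tests over exhaustive enumerations.  Minimal separators are enumerated by
neighborhood expansion (seed with N(C) for components C of G−N[v], close
under the substitution step), cross-checked against a brute-force subset
scan on small random graphs.

Chordality uses maximum-cardinality search with the fill check; on failure
a chordless cycle (length ≥ 4) is extracted as a witness by taking an
induced path between the two offending neighbors avoiding the rest of the
closed neighborhood.  Clique trees are maximum-weight spanning trees of
the clique-intersection graph, with the coherence property verified before
return.

`cuts_to_triangulation` implements the constructive bridge from a
minimized, ordered, complete parallel legal cut set to a legal
triangulation: per cut, sole-slice internal edges contribute (x_i, y_i)
pairs split across the two components (or, when an earlier cut already
differentiates the edge, the single endpoint lying in the unique component
of the earlier cut's removal that meets the later cut); sole-slice leaf
edges contribute their internal endpoint to both sides; multi-edge slices
contribute their common vertex to both sides.  Saturating G(P) with every
{X_F, Y_F}, the interpolating families O_F, and each leaf's open
neighborhood yields the triangulation, which is then *verified* (chordal,
no clique mixing an internal display edge with another display edge, no
leaf-incident fill-in) — the theory says verification cannot fail on valid
input, so a failure is reported as an internal error.  The cut order is
the canonical sorted-edge-list order for reproducibility; the construction
is order-dependent but any fixed order is valid.

## The cut function and edge splitting

For an AST S, `cut_function` computes Ψ mapping each edge e = {u, v} of S
to the input edges for which e is the agreement edge (input split sides
contained in L_u and L_v respectively), together with the label sides and
the Steiner vertex sets V_u, V_v.  Ψ(e) is always a cut; minimality is
checked by component count.  `split_edge_at` performs the supporting
surgery — reattaching the far-side subtrees component-wise to the near
endpoint — and `normalize_ast` iterates it (largest |Ψ| first) until every
Ψ value is a minimal cut.  These utilities are not used by the decider;
they exist so the supporting theory (agreement preservation, restriction
invariance, termination, and the fact that the normalized internal-edge Ψ
values form a valid agreement cut set) is itself testable.  One degenerate
case is handled explicitly: if the attachment endpoint is a labelled leaf,
a fresh internal vertex is interposed so the result remains a phylogenetic
tree.

## Synthetic data

`random_profile` draws a random binary supertree (sequential leaf
attachment at a uniformly chosen edge — deliberately simple, not uniform
over topologies), restricts it to per-tree random label subsets, then
optionally (a) contracts each internal edge independently with a given
probability, producing profiles that are compatible by construction but
generally lack an AST, or (b) swaps two leaf labels in one tree, which
breaks compatibility with high probability.  Defaults (8 labels, 3 trees,
subsets of 6, no contraction, no perturbation) keep display graphs within
the enumeration guard while leaving room for non-trivial overlap; sweep
tests shrink to 5–7 labels so that exhaustive enumeration, the brute-force
oracles, and several hundred repetitions stay fast on one core.

What the generator does *not* emulate: estimation error (inputs are exact
restrictions of a true tree, possibly coarsened), rogue taxa, biased taxon
sampling, or any process realism (no birth–death or coalescent model).
Passing tests therefore demonstrate correctness of the combinatorics on
the stated regimes — restriction-only, contraction, label-swap — not
robustness to noisy real gene trees, which the underlying decision
problems do not address.

The two figure fixtures self-verify on construction against every printed
cut and split of the worked examples; a mismatch raises instead of being
patched.  The second figure's exact topology is not present in the
extracted source, so the fixture is a reconstruction constrained by the
printed cut lists (documented in its docstring and validated by the same
self-checks, including an AST existence check).

## Numerical and determinism choices

There is no floating-point anywhere; determinism is the only "numerics"
concern.  Canonical forms: splits order their sides lexicographically;
cuts sort by edge lists; cut sets, Newick output (children ordered by
smallest descendant label), and generated profiles are byte-stable for a
given seed.  Tree popping processes splits in canonical order — the
splits-equivalence theorem makes the result order-independent, asserted by
a shuffle test.  All randomness flows through explicit `random.Random`
seeds; nothing touches global state.

## Known limitations

- Everything is desk-scale: minimal-cut enumeration is exponential in the
  display graph size (guard: 18 vertices), and the backtracking search is
  exponential in the number of internal input edges.  No fixed-parameter
  or heuristic algorithms are provided.
- Parallelism is undefined for non-minimal cuts and is rejected, not
  guessed; the definition's apparent asymmetry is computed both ways for
  minimal cuts and an asymmetric case would raise loudly (none has been
  observed).
- The AST returned is one witness; uniqueness is neither claimed nor
  checked.
- The triangulation→cut-set direction is not implemented.
- Branch lengths and internal node labels in Newick input are parsed and
  discarded; only topology is semantic.
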