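# supercut

Deciding **supertree compatibility** and **agreement** for profiles of
unrooted phylogenetic trees, through minimal cuts of the display graph.

## The problem

A *profile* is a collection of unrooted, leaf-labelled trees whose label
sets may overlap — typically gene trees over partially overlapping taxon
samples.  A *supertree* is a tree on the union of all labels.  Two classic
questions:

- **Compatibility** — is there a supertree *S* that *displays* every input
  *T*, i.e. Σ(T) ⊆ Σ(S|ℒ(T))?  Polytomies in the inputs are treated as
  soft: the supertree may refine them.
- **Agreement** — is there a supertree with Σ(S|ℒ(T)) = Σ(T) for every
  input (an *agreement supertree*, AST)?  Polytomies are hard facts.

Both problems are NP-complete in general.  They have a strikingly
combinatorial characterization on the **display graph** G(P) — the union of
the input trees with equal-label leaves identified:

> A profile is compatible iff G(P) admits a *complete* set of pairwise
> *parallel* *legal* minimal edge cuts; it has an agreement supertree iff
> some such set additionally uses at most one edge per input tree in every
> cut.

Here a cut F is *legal* if, per input tree, its edges share a vertex;
*nice* if additionally every component of G(P)−F keeps an edge; two minimal
cuts are *parallel* (non-crossing) if removing one leaves the other inside
a single component; and the set is *complete* if every internal edge *e* of
every input tree is the **sole** edge of its tree in some member cut.  Each
nice minimal cut F induces a split σ(F) of the label set (the labels of the
two components), and the splits Σ(𝔉) of a complete parallel set are
pairwise compatible — the supertree falls out of the splits-equivalence
theorem.  The same objects live on the *edge label intersection graph*
LG(P) (the line graph of G(P)) as legal minimal separators, which connects
the cut view to chordal-graph theory: from a complete parallel legal cut
set this package also constructs a **legal triangulation** of G(P)
directly, by saturating per-cut separator pairs (X_F, Y_F) and their
interpolating families O_F.

`supercut` implements all of this as exact, certificate-producing deciders
at desk scale, with brute-force supertree enumeration as an independent
oracle.

## Worked example

The bundled two-tree fixture (`supercut.fig1_profile()`) reproduces the
canonical worked example: tree 1 = `((a,b,c),f,(d,e))`, tree 2 =
`((a,b),c,(d,(f,g)))`.

```python
>>> import supercut as sc
>>> profile = sc.fig1_profile()
>>> decision = sc.decide_compatibility(profile)
>>> decision.status
'yes'
>>> sorted(map(str, decision.certificate.splits))
['abcde|fg', 'abcfg|de', 'abc|defg', 'ab|cdefg']
>>> sc.write_newick(decision.certificate.supertree)
'(a,b,(c,((d,e),(f,g))));'
>>> sc.decide_agreement(profile).status
'no'
```

The certificate's four cuts induce exactly the four splits above; the
supertree built from them displays both inputs.  The same profile has *no*
agreement supertree — no complete parallel legal cut set exists with at
most one edge per tree in every cut — while the second fixture
(`sc.fig2_profile()`) does, and `decide_agreement` returns the AST.

From the shell:

```sh
supercut compat --trees profile.nwk --certificate cert.json --supertree out.nwk
supercut agree  --trees profile.nwk --ast ast.nwk
supercut verify --trees profile.nwk --certificate cert.json
supercut triangulate --trees profile.nwk --out tri.tsv
supercut synth  --recipe recipe.json --out profile.nwk
```

Exit codes: `0` compatible / AST exists / certificate valid, `1` negative
answer, `2` unknown (guard exhausted) or input error.  `verify` re-checks
certificates with a definition-level code path independent of the search.

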