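# Methods

## Scope and assumptions

`fintegrate` integrates presence/absence trait statements, curated at mixed
taxonomic ranks and often expressed indirectly, with a rooted species-level
tree, and reconstructs ancestral states by unordered parsimony. Assumptions
baked into the design:

* characters are binary structure presence/absence (the matrix symbols carry
  provenance, not extra biological states);
* the tree is rooted and may be arbitrarily multifurcating; branch lengths are
  neither required nor used (the cost model is unit-cost and symmetric);
* taxonomy ranks form the ladder species < genus < family < higher; only genus
  and family participate in propagation;
* annotations name terms in a typed anatomy graph whose `part_of` and `is_a`
  relations are acyclic.

## Inference rules

Presence and absence propagate asymmetrically over the anatomy graph:

| fact | propagates along | direction |
|---|---|---|
| presence (any non-absence quality on E) | `part_of`, `is_a` | subject → object (part to whole, subtype to supertype) |
| absence of W | `part_of`, `is_a`, `depends_on`, `develops_from` | object → subject (whole to part, class to subtype, required to dependent, precursor to derivative) |

The four non-inferences (supporting structure ↛ dependent structure present;
whole ↛ parts present; precursor ↛ derivative present; part absent ↛ whole
absent) fall out of the direction rules. Structural-necessity knowledge
("paired fins never occur without their girdle") is modeled as explicit
`depends_on` edges rather than recovered from ontology axioms: an explicit
edge list is inspectable and testable.

One genuinely open choice: whether absence should flow across `is_a` at all.
We propagate absence from a class to its subtypes (absence of "paired fin" in
a taxon entails absence of each paired fin), which mirrors subsumption
semantics, and never in the subtype-to-class direction. The closure is a
worklist iteration to fixpoint; every inferred annotation records its
derivation chain of (subject, relation, object) steps.

## Matrix coding and conflicts

A cell aggregates all annotations whose entity is the character term or an
`is_a` descendant of it; part-level statements reach the cell only through the
inference closure. Coding: an author assertion wins (`0`/`1`) even when the
same state is also inferable; inference-only cells are `2` (present) or the
rare `3` (absent, produced and logged rather than reserved silently); cells
supported in both states are `0&1`.

Both-states cells are classified by rank and provenance: above species rank
they are *apparent polymorphisms* (the member species carrying each state are
unidentified) and are replaced by `?` before propagation; at species rank,
both-asserted cells are *true polymorphisms* and mixed asserted/inferred cells
are *assertion-vs-inference conflicts*. Both species-rank kinds are retained
(flagged) through propagation — their presence blocks overwriting — and are
down-coded only at tree-merge time: conflicts become missing, polymorphisms
become the ambiguous state set {0,1}. This two-stage treatment reproduces
both operational behaviours one might want from such records (they do not
propagate wrong states, yet they still shield their species from propagation).

## Propagation

Genus- and family-level states are copied to member species that lack their
own value for the character, per cell. Precedence when genus and family
disagree is nearest-ancestor (genus) — the taxonomically least risky choice —
with the disagreement logged per affected species. Ranks above family never
propagate: the expectation of state change grows with divergence time.
Existing species data are never replaced; blocked overwrites are logged with a
conflict category (vs. asserted or vs. inferred data) when the states are
disjoint. Each propagated cell records its source taxon so downstream audits
of risky propagations remain possible. Propagation is idempotent (the output
matrix is species-only, so a second pass finds no sources).

## Reconciliation

Two passes: shared external integer identifiers first (robust to spelling
differences), then normalized exact name equality among the remainder.
Normalization maps underscores to spaces, collapses whitespace, and strips
trailing subspecies epithets — but only tokens that plausibly are epithets
(lowercase alphabetic, length ≥ 2), so that mangled or annotated labels stay
distinguishable. Matching is case-sensitive after normalization. Anything
ambiguous — duplicate IDs on one side, homonymous tip labels, one name on two
taxa — is flagged and left unmatched; a wrong match is worse than a missing
one. Unmatched matrix taxa are categorized as fossil (extinct flag),
unconventional name (fails the strict `Genus species` pattern), or other.

## Parsimony engine

The dynamic program is the standard Sankoff recursion on the rooted
(possibly multifurcating) tree with unit costs, exact on polytomies. Tips
carry state *sets*; missing and polymorphic tips cost zero under either
parent state. Only internal nodes are labeled, so tips never multiply the MPR
count. Alongside the cost the DP carries:

* **counts** of minimum-cost sub-labelings (products over children of sums
  over cost-minimizing child states) — Python integers throughout, no
  floating point on any counting path;
* **gain bounds**: per node and state, the min and max number of 0→1 edges
  among minimum-cost sub-labelings. Child contributions are independent given
  the parent state, so sums of per-child minima/maxima are exact. Loss bounds
  follow as `length − gain_max` / `length − gain_min`, because gains and
  losses sum to the length in every MPR.

Uniform MPR sampling draws the root state, then each internal state given its
parent, with probability proportional to sub-counts; every sample is verified
to achieve the minimum length. "Regain" is operationalized as a 0→1 edge in
an MPR; when the root state is ambiguous, gains are counted per that MPR's own
root labeling (in the planted-history test conditions the root is always
unambiguously presence).

Polytomies are treated as hard for the DP. The soft-polytomy view is provided
by replicate random resolutions: each polytomy is resolved by repeatedly
joining two uniformly chosen child lineages (seeded), the exact gain bounds
are recomputed on the binary tree, and the minimum gain count across
replicates bounds the number of regains the data actually force. Note the
direction of the resolution effect: resolving can only *shorten or preserve*
the parsimony length (any labeling of the collapsed tree extends to the
resolved one at equal cost), which is exactly why resolutions can eliminate
spurious regains that a hard polytomy appears to require.

Degenerate inputs: an all-missing tip set yields length 0 with a warning; a
sample size ≤ 0 and an empty resolution-replicate count are rejected.

## Synthetic data

The generator emulates the shape of real integration inputs: a 3-rank
taxonomy under one supra-familial root; annotations at mixed ranks with
direct and indirect (part-quality, girdle-absence) statements; injected
species-level contradictions; and a tree that honours taxonomy monophyly but
carries polytomies, deterministic `_x` name perturbations, and data-free novel
tips. Defaults (8 families, 2–4 genera each, 2–6 species per genus, ≈100–200
species; 5 planted losses and 1 regain per character; 30% indirect
statements; 20% higher-rank statements; 20% of internal nodes collapsed; 80%
of records with external identifiers) were chosen once as a realistic
desk-scale miniature of a curated trait compilation — large enough that every
pipeline stage has real work, small enough that brute-force oracles stay
feasible.

Planted histories start from presence at the root. In sparse mode losses are
mutually non-nested and never share a parent node, and each regain is placed
inside a distinct loss clade behind at least three off-path absent lineages.
That last condition is what makes the history identifiable: explaining those
lineages without a gain costs at least three changes where loss-plus-regain
costs two, so every MPR spends exactly one gain inside each regain-hosting
clade, and the end-to-end reconstruction must return length = losses +
regains with exact gain bounds equal to the planted regain count. Placements
are additionally verified against the parsimony engine and retried (bounded,
seeded) on failure; an impossible request raises an error rather than being
silently relaxed. The indirect-statement fraction applies to both polarities
(part-quality for presence, girdle-absence for absence) so both closure
directions are exercised end to end.

What the generator does **not** emulate: real ontology breadth (the anatomy
graph is a fixed fin template), synonymy and authority strings in names,
fossil-specific sampling, rate heterogeneity, or branch lengths. Passing the
recovery tests therefore demonstrates correctness of the integration and
reconstruction machinery under clean identifiable conditions — not robustness
to curation noise beyond the perturbations modeled here.

## Numerical and engineering choices

* Every random stream is an explicit `random.Random` seeded from a scenario or
  pipeline master seed (stage seeds derive by fixed offsets), so reruns are
  byte-identical.
* MPR counts use arbitrary-precision integers end to end (counts grow
  multiplicatively with tree size and routinely exceed floating-point
  precision on real-scale trees); the enumeration cross-checks guarantee the
  combinatorics independent of magnitude.
* TSV is the native interchange format for every tabular artifact; the matrix
  round-trips symbols and flags exactly. NEXUS export uses symbols `0 1 2`,
  `{0 1}` for polymorphism, `?` for missing, with inferred-only absence
  written as `0` (with a warning) since downstream parsimony treats them
  identically.
* The NeXML reader accepts a configurable metadata predicate for cell
  provenance because no standard predicate exists; unparseable provenance
  downgrades the cell to provenance-unknown instead of failing the parse.

## Known limitations

* Characters are binary; multistate characters would need a different coding
  layer (the DP itself generalizes, the matrix symbols do not).
* Reconciliation is deliberately conservative: no fuzzy matching, no synonym
  services; taxa renamed between sources stay unmatched.
* The regain bound from random resolutions is an upper-bound search by
  sampling; it is not guaranteed to find the global minimum over all
  resolutions of large polytomies.
* Propagation trusts the taxonomy: a higher-rank statement reaches every
  member species the taxonomy lists, including species the original author may
  not have examined. The per-cell source records exist precisely so such
  propagations can be audited.
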