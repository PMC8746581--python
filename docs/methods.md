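# Methods

## The model

A structure record is a `Glycan` with at most one `GlycanCore` and at most
one `GlycanBag` (both relationships functional; a record may also be
id-only, carrying no structural encoding at all). The core is the
unambiguously connected part, a rooted tree whose nodes are `Residue`
objects; the bag collects the substructures that are known to be present
but whose attachment to the core is unknown — each `GlycanBagItem` is
itself a rooted subtree parsed from one GlycoCT UND section, together with
its attachment-candidate residue ids and its statistical weights. The
weights and candidates are stored for completeness but carry no matching
semantics: an item is, by definition, unattached.

A residue hosts up to two *building blocks*: a base (the monosaccharide
skeleton — basetype string such as `dglc-HEX`, anomer, ring bounds,
modifications) and a substituent (`n-acetyl`, `sulfate`, ...). Two blocks
connected by a fully explicit linkage merge into one *composed* residue
when a composed-residue rule fires; otherwise the substituent stays a node
of its own. Every residue carries a composition class grouping
mass-isomeric blocks (Hex = Glc/Gal/Man; dHex = Fuc/Rha; HexNAc; Neu5Ac;
...), enabling isomer-agnostic search.

Child order inside a residue is an encoding artifact: chemistry does not
order branches, so children are compared as multisets everywhere
(`isomorphic` canonicalizes subtrees bottom-up; the builder stores children
in a deterministic sort order so that rebuilds assign identical preorder
ids, which keeps RDF URIs and match reports stable).

## GlycoCT dialect

The reader targets GlycoCT{condensed}: RES/LIN sections, optional UND
sections, exact uppercase headers, blank lines ignored. Unknown tokens are
mapped to explicit sentinels and never silently defaulted: anomer `x`,
position `-1` → `UNKNOWN`, alternative positions `3|6` → the set {3, 6},
ring bound `x`. REP (repeat-unit) and ALT sections are rejected with a
typed error — repeats are outside the tree model. Carbon positions are
1-based throughout; `UNKNOWN` is a distinct sentinel, never 0 or −1
internally. A multi-record corpus is a TSV of
`structure_id<TAB>glycoct-with-newlines-as-spaces`; an empty GlycoCT field
yields an id-only record. When a UND block carries more than one
SubtreeLinkage entry only the first is kept (the attachment stays unknown
either way).

Serialization emits sections in RES, LIN, UND order with entries in
ascending index order, so identical input produces byte-identical output;
parse∘serialize is identity up to index renumbering, verified as a
property test via the isomorphism oracle.

## Rule tables

Rules are plain JSON, user-replaceable as a whole (CLI `--rules`). A
composed-residue rule has five fields — first block (base) name, second
block (substituent) name, the two carbon numbers of their linkage, and the
composition class of the merged residue. A rule only fires on single,
explicit carbon positions: a 2+1 rule never fires on `(-1+1)` or `(2|4+1)`,
because merging under uncertainty would fabricate knowledge. Composition
rules map a block name (optionally with required modifications, e.g.
`lgal-HEX|6:d` for fucose) to a class; the most specific match wins and
anything unmatched is `UNDEFINED`.

The shipped default table covers the common animal donor residues: GlcNAc,
GalNAc, ManNAc, GlcN/GalN, Neu5Ac and Neu5Gc compose; Hex, dHex, Pent,
HexA, HexN, Kdn and the substituent classes resolve. It is a versioned
reconstruction intended as a sensible default, not an exhaustive
vocabulary. Phosphate and sulfate deliberately never compose: keeping them
as separate nodes is what makes "structures with exactly GlcNAc and
phosphate"-style searches expressible. When one base has several
substituent children matching rules, the lowest-keyed edge (by parent
carbon, then entry index) merges and the rest stay separate nodes — a
residue hosts at most one substituent; the tie-break is deterministic and
order-independent (verified by shuffling LIN entries).

## Pattern notation and matching

Patterns use a condensed-IUPAC-flavoured notation. Tokens are common
residue names (resolved to basetype+substituent constraints: `GlcNAc` =
`dglc-HEX` with required `n-acetyl`), composition classes (`Hex`, `dHex`),
substituent names (`phosphate` — matches substituent-only nodes), or `?`
(any residue). `Fuc` is resolved at composition level (dHex) because the
basetype string `lgal-HEX` alone cannot be told apart from L-galactose
without the 6:d modification. An optional `(<anomer><child>-<parent>)`
annotation constrains the linkage to the parent and the node's anomer; any
element may be `?`.

Bracket binding is the one place where the grammar departs from plain
IUPAC, and it is deliberate: a branch **with** a linkage annotation binds
IUPAC-style to the residue at its right (`...[Fuc(a1-3)]GlcNAc` puts the
fucose on the GlcNAc), while an annotation-free branch decorates the
residue at its **left** (`Gal[Fuc]GlcNAc[Fuc]` is a fucosylated galactose
on a fucosylated GlcNAc — the natural reading of the linkage-free Lewis
probe, and the only reading under which that probe retrieves Lewis B/Y
structures). Whitespace between tokens is ignored, so the right-binding
form without annotations can be written `Gal GlcNAc[Fuc]`.

Matching is rooted, parent→child directed (glycosidic donor→acceptor), and
unordered: pattern children map injectively onto residue children by
backtracking. The three options:

* anchor `anywhere` / `root` / `whole` (`whole` additionally requires equal
  child counts at every node, i.e. a bijection onto the entire tree);
* mode `strict` / `fuzzy`. Fuzziness is two-sided for UNKNOWN but one-sided
  for names: UNKNOWN data satisfies any constraint in fuzzy mode, while a
  named data value never satisfies a different named constraint in either
  mode. Position sets: a single query position matches a data set by
  membership (GlycoCT's `3|6` is a disjunction); a query set requires
  equality in strict mode and non-empty intersection in fuzzy mode;
* scope `core` / `bag` / `both`; one pattern tree never spans the core→bag
  boundary.

These semantics give the monotonicity laws checked in the test suite:
strict matches ⊆ fuzzy matches, and whole ⊆ root ⊆ anywhere as glycan-id
sets.

`brute_force_match` is the testing oracle: it enumerates every injective
mapping of pattern nodes onto the residues of a tree (guarded at 12
residues by default) and filters by the same constraint predicates. It
shares the per-node/per-edge predicates with the production matcher — the
independence lies in the search strategy — and the two are required to
agree exactly on hundreds of random pattern/structure pairs.

`match_bag_multiset` implements bag-only search ("at least one free Fuc
item and one free GlcNAc item"): an injective assignment of patterns to
distinct bag items. `chain_search` returns *maximal* parent→child chains
of at least k residues satisfying a node constraint; maximality avoids
counting every sub-path of a long run when the question is "are two or
more sialic acids consecutively linked".

The catalog (`run_catalog_query`) composes these primitives into the
standard validation queries: counts 1–16 (root-substituent structures,
distinct base/substituent types, structures starting with Fuc/Man/Xyl,
at-least-k and exactly-k bag-size histograms, core-less records, census
counts) and Q1–Q6 (whole-core N-glycan core match, exact
GlcNAc+phosphate composition, bag listings, consecutive sialic acids with
an optional O-linked Core 1 conjunction, single-residue cores).
Queries 8–10 ("starts with Fucose/Mannose/Xylose") test the core root: 8
at composition level (dHex), 9 and 10 at basetype level, since mannose
shares its composition class with the other hexoses. Q6 filters
single-residue cores; the protein-linkage context that would identify
O-linked monosaccharides definitively is not part of the model. The
shipped di-sialyl-Tn pattern (two Neu5Ac on a GalNAc root, positions
unconstrained) is marked provisional in the pattern library.

## RDF export

Each built Glycan becomes a set of typed individuals under a
caller-supplied absolute base URI; the class/property vocabulary lives in a
documented placeholder namespace (`https://glycantree.example.org/model#`).
Residues link to Base/Substituent individuals carrying
name/anomer/position literals; roots are additionally typed `ResidueRoot`;
bag items are `GlycanBagItem`s inside the `GlycanBag`. Linkage labels are
stored on the child residue (every non-root has exactly one inbound edge).
`hasGlycanCore`/`hasGlycanBag` are functional by construction. Output is
sorted N-Triples (byte-stable, diffable) or Turtle. Ancestor/descendant
closures are derivable and therefore not materialized by default
(`materialize_closures=True` opts in). `triple_census` predicts
per-predicate counts in closed form — #hasBase = residues with a base,
child links = Σ(tree size − 1), etc. — and the export must reproduce it
exactly; `import_glycan` reconstructs an isomorphic Glycan from an exported
document, closing the round-trip.

## Synthetic corpora

The generator grows random but chemically plausible trees: roots drawn
from the common reducing-end residues (GlcNAc, GalNAc, Glc), children
attached at free carbons (no two children on one carbon; carbons already
spent on the substituent of a composed residue are not offered), sialic
acids only terminal, phosphate/sulfate as leaf decorations. Defaults: 2–7
residues per structure; residue alphabet weighted toward Gal/Man/GlcNAc;
branching probability 0.4; unknown-linkage and unknown-anomer
probabilities 0.15 each; UND-block count distribution placing 28% of
structures in the "has undefined sections" class (1 block 10%, 2 blocks 7%,
..., 9 blocks 0.1%) — the ambiguity profile of a curated glycan database.
Randomness uses one named stream per purpose, spawned from the master
seed, so seeded runs are byte-identical.

Motif planting grafts a concrete Lewis A/B/X/Y instance at a random free
carbon (raising a typed error if no acceptor exists); with
`blank_linkages` a random non-empty subset of the instance's positions and
anomers is set to unknown, producing structures that strict patterns miss
but the linkage-free fuzzy probe still finds. Benchmark corpora
(`make_benchmark`) plant `round(n · frequency)` instances (half blanked)
and guarantee clean truth labels by *rejection*: a background draw that
happens to contain the fuzzy probe motif is re-drawn, with the check done
by the brute-force oracle so the production matcher is never used to
define its own truth. Labels are per-structure.

What the generator does **not** emulate: the composition distribution,
branching statistics or residue inventory of any real database; repeat
units; multi-antenna N-glycan biosynthesis constraints. Passing tests
therefore demonstrate correctness of parsing, building, matching and
export under controlled ambiguity — not retrieval statistics on real data.

## Numerical and procedural choices

* Problem sizes in the test suite and the acceptance script — 500 oracle
  pairs, five 200-structure benchmark corpora, 1000 round-trip structures,
  100 RDF exports — keep a full run in seconds while exercising every code
  path at the scale the benchmark design calls for.
* The brute-force guard (12 residues) bounds the oracle's permutation
  enumeration; benchmark rejection uses a raised guard (40) since its
  pattern is small and trees are shallow.
* Degenerate inputs: a single-residue structure is a one-node core; a
  structure whose main RES section is empty is valid only if UND blocks
  carry the residues (a composition-only record — no core, bag items
  only); an id-only record has neither. Cycles, dangling indices,
  duplicate indices, multiple roots and out-of-range UND weights are typed
  parse errors; `validate` returns them as issue records instead of
  raising.
* Tie-breaks are deterministic everywhere (child sort keys, merge order,
  result ordering by glycan id → location → mapping), making CLI output
  reproducible byte-for-byte for a given seed.

## Known limitations

* The composed/composition rule tables are a reconstruction covering the
  common animal residue space; unusual residues fall back to separate
  nodes and `UNDEFINED` composition rather than failing.
* Repeat-unit (REP) and ALT structures are rejected, not modeled.
* Bag items' statistical weights and attachment candidates are carried but
  not used in matching.
* No scoring or ranked retrieval: matching is exact under the declared
  wildcard semantics, and no edit-distance approximation is offered.
* The pattern vocabulary resolves a fixed set of common names; unknown
  names are errors rather than guesses.
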