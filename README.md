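# glycantree

A tree+bag knowledge model for **ambiguous glycan structures**, with
GlycoCT{condensed} parsing, composed-residue rules, precise and fuzzy
substructure search, and RDF export.

## The problem

Glycans are branched tree-like carbohydrates. The structures deposited in
public repositories are solved by experimental techniques of very uneven
resolution: anomeric configurations come out as α, β or *unknown*; carbon
attachment positions may be a number, a disjunction ("3|6") or unknown
("-1"); and whole substructures may be known to be present without anyone
knowing where they attach (GlycoCT *UND* sections — in curated databases
more than a quarter of all structures carry them). Classical substructure
search breaks down on such records: a query with explicit linkages silently
misses every structure whose linkages were never determined.

`glycantree` is for glycoinformaticians and database curators who need to
search and compare structures *independently of how well they were
resolved*. It models each structure as:

* a **core** — the unambiguously connected part, a rooted tree of residues
  (`GlycanCore`), and
* a **bag** — the multiset of substructures whose attachment to the core is
  unknown (`GlycanBag`, one `GlycanBagItem` per UND section),

where each **residue** hosts a base (monosaccharide skeleton), a substituent
(n-acetyl, sulfate, phosphate, ...), or both merged into one *composed*
residue (GlcNAc = Hexose + N-acetyl at carbons 2+1) by an editable JSON rule
table. Every residue additionally carries a **composition class** (Hex,
dHex, HexNAc, Neu5Ac, ...) grouping mass-isomeric building blocks, so a
query can ask for "a deoxyhexose" without naming fucose.

## Matching semantics

Patterns are written in a compact bracketed notation
(`Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc`; annotation-free branches like
`Gal[Fuc]GlcNAc[Fuc]` leave all linkages unconstrained) and matched as
unordered labeled subtrees with three orthogonal options:

* **anchor** — `anywhere` | `root` (core/bag-item root) | `whole`
  (bijection onto an entire tree);
* **mode** — `strict` (an unknown data value fails any named constraint) or
  `fuzzy` (unknown satisfies everything; position sets match on non-empty
  intersection). In both modes a *named* mismatch never matches: fuzziness
  models missing knowledge, not Gal≈Glc;
* **scope** — `core` | `bag` | `both` (a single pattern never spans the
  core→bag boundary).

A brute-force enumeration matcher serves as an independent testing oracle,
and a synthetic-corpus generator with planted Lewis-antigen motifs and
controlled ambiguity makes the whole pipeline testable without any external
database.

## Worked example

```python
import glycantree as gt
from glycantree.query import library_pattern

rules = gt.default_rules()

text = "RES 1b:x-dglc-HEX-1:5 2s:n-acetyl LIN 1:1d(2+1)2n"
glycan = gt.build_glycan(gt.parse_glycoct(text), rules, id="example")
(residue,) = gt.residues(glycan)
print(f"residues: {len(gt.residues(glycan))}")
print(f"base: {residue.base.name} (anomer {residue.base.anomer})")
print(f"substituent: {residue.substituent.name} at carbons "
      f"{residue.substituent.attach_position_on_base}+{residue.substituent.child_position}")
print(f"composition: {residue.composition}")

records, glycans, labels = gt.make_benchmark(200, motif_frequency=0.04, seed=1)
probe = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy")
hits = sorted(g.id for g in glycans if gt.match(probe, g))
truth = sorted(l.structure_id for l in labels if l.is_positive)
print(f"planted: {len(truth)}  found: {len(hits)}  identical: {hits == truth}")
```

prints

```
residues: 1
base: dglc-HEX (anomer x)
substituent: n-acetyl at carbons 2+1
composition: HexNAc
planted: 8  found: 8  identical: True
```

The two RES building blocks of the GlcNAc record collapse into **one**
composed residue of class HexNAc with the anomer left unknown — the model
keeps the encoding's granularity without fragmenting the chemistry. On a
200-structure corpus with 8 planted Lewis B/Y motifs (some with their
linkages blanked to "-1"), the linkage-free fuzzy probe `Gal[Fuc]GlcNAc[Fuc]`
retrieves exactly the planted structures: no false positives, no false
negatives.

## Command line

```sh
glycantree generate --n 200 --seed 1 --motif-frequency 0.04 --out corpus
glycantree search   --corpus corpus.tsv --pattern "Gal[Fuc]GlcNAc[Fuc]" --mode fuzzy
glycantree stats    --corpus corpus.tsv --query 12
glycantree export   --corpus corpus.tsv --base-uri https://example.org/kb/ --out rdf/
glycantree validate structure.glycoct
```

Corpora are tab-separated files (`structure_id<TAB>glycoct`, newlines
encoded as spaces). `stats` exposes the quantitative catalog (queries 1–16:
root-substituent counts, distinct base/substituent types, bag-size
histograms, ...) and the qualitative catalog (Q1–Q6: exact N-core matches,
exact composition, bag listings, consecutive sialic-acid chains, ...).

## Layout

| module | purpose |
| --- | --- |
| `glycantree.glycoct` | GlycoCT{condensed} parse/serialize/validate + corpus container |
| `glycantree.model` | `Glycan`/`GlycanCore`/`GlycanBag`/`Residue` types, traversal, isomorphism |
| `glycantree.rules` | composed-residue + composition rule tables (JSON, user-replaceable) |
| `glycantree.builder` | raw sections → model (merging, compositions, bags) |
| `glycantree.query` | pattern notation, strict/fuzzy matcher, brute-force oracle, catalogs |
| `glycantree.rdf` | RDF individuals export/import, closed-form triple census |
| `glycantree.synth` | synthetic corpora, motif planting, labeled benchmarks |
| `glycantree.cli` | `glycantree` command |

Design notes, parameter defaults and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
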