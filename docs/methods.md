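# Methods

## The problem

Comparative biology needs one anatomy ontology that spans taxa: phenotype
annotations made against a teleost-specific class and gene-expression data
annotated against an amphibian-specific class cannot be compared unless both
resolve to a shared cross-species class. The historical answer was to fold
several group-specific multi-species anatomy ontologies (msAOs — a teleost
AO, an amphibian AO, a vertebrate skeletal AO, and a homology-grouping
vocabulary) into a single cross-species target, leaving behind obsolescence
records so that every legacy identifier still resolves. `anatomerge`
mechanizes that workflow end to end on ontologies in OBO flat-file form.

## The merge decision tree

Every non-obsolete source class is handled exactly once:

1. **Mapped classes** (a curated equivalence entry exists) are *merged*.
   The pre-existing target class absorbs only annotation-level payload:
   - every translated source axiom missing from the target becomes a
     *structured comment* (`MERGE NOTE [<source-id>]: …`), never a logical
     axiom — a relationship valid for one taxon (a teleost quadrate
     overlapping a particular joint) may not hold across the target's full
     taxonomic range;
   - the source's text definition is attached as an *external definition*
     annotation when its whitespace-normalized text differs from the
     target's primary definition;
   - the source label becomes an EXACT synonym (and source synonyms are
     copied) unless already present under case-insensitive comparison, each
     carrying the source id as synonym xref;
   - the source id is added as an xref on the target.
2. **Unmapped classes** are *migrated*: a new identifier is minted in a
   per-source ID space and the class copied verbatim (label, definition,
   synonyms, xrefs, subsets) into the extension (Ext) ontology; its axioms
   are rewritten through the combined mapping (curated equivalences plus
   the ids minted in the same run), so mutually referencing unmapped
   classes stay connected. Axioms whose object has no image are emitted as
   drop records, never silently discarded.
3. **Pre-obsolete classes** are skipped; their existing `replaced_by`
   chains are copied into the stub output so chain-following QC still works.

In both handled cases the source class is obsoleted with exactly one
`replaced_by` pointing at the target or minted id, and stripped of logical
axioms. Validation (unknown ids, one-to-many mappings, obsolete targets)
and all minting happen before any mutation, so a failing run aborts cleanly.

### ID spaces

Migrated ids are `lead digits + preserved tail of the source number`,
seven digits total in the target namespace: lead `2` with a six-digit tail
for the teleost AO (TAO:0001611 → UBERON:2001611), lead `3` for the
amphibian AO (AAO:0000680 → UBERON:3000680), lead `40` with a five-digit
tail for the skeletal AO (VSAO:0000093 → UBERON:4000093). Classes new to
the whole ecosystem draw monotonically from the `42nnnnn` space
(counter 22 → UBERON:4200022). Minting is injective per run; collisions
with declared ids raise before mutation.

### Taxonomic equivalence

A taxonomic mapping (`A and part_of some Taxon EquivalentTo B`) is not
expressible in the supported OBO tag subset, so it lives only in the
tab-separated mapping sidecar (`taxon` column required exactly for
taxonomic rows). Direct equivalences additionally surface as xrefs on the
merged target class.

## Candidate alignment

`propose_candidates` mechanizes the manual comparison phase as an advisory
ranking; the merge itself consumes only the curated table. Evidence classes
and scores: exact label or xref 1.0, exact synonym 0.9, definition token
Jaccard ≥ 0.5 (configurable) 0.8. The numeric values are ranks, not
probabilities; the only invariant relied on is that 1.0 occurs exactly for
label/xref evidence. Comparison is case-insensitive after whitespace
normalization. Ambiguous labels (the 'manubrium' problem — a label unique
within one taxon's ontology colliding with an unrelated structure in the
merged scope) are deliberately surfaced to curators rather than resolved.

## Design-pattern rewrites

- **Joint flip**: `element overlaps joint` (either asserted direction)
  becomes `joint connected_to element`. Joints are thereby defined by the
  elements they connect, which is stable across taxa whose skeletal
  connectivity varies.
- **Attachment normalization**: `tooth part_of|connected_to|overlaps bone`
  becomes `tooth attaches_to bone`, giving dentition one uniform query
  pattern whether the teeth sit on a jaw or a pharyngeal bone.

Pattern scope is supplied as explicit class filters (label predicates or
id lists): deciding *which* classes are joints or teeth is curatorial.
Both rewrites are idempotent, conserve the axiom count, commute on their
disjoint property scopes, and log every change.

## Pre-reasoned closure and slims

The "simple" release product materializes entailed edges over three
properties (`is_a`, `part_of`, `develops_from`) using a binary composition
table (`is_a∘part_of → part_of`, etc.), iterated semi-naively to a least
fixed point. This is deliberately not a DL reasoner: no property chains
beyond binary composition, no disjointness. `is_a` cycles are tolerated
but reported with their members.

Slims keep only classes carrying a subset tag and re-wire relations
through the removed classes using the closure. By default redundant edges
(derivable by composing two kept edges) are dropped; because the candidate
edge set is composition-closed among kept nodes, the two-step redundancy
test is complete, and on a pure subclass graph the result coincides with
the transitive reduction (checked against networkx's implementation in the
tests). A `minimal=False` / `--keep-redundant` mode emits every entailed
edge instead, since release practice has used both shapes.

## QC checks

Four release-gate checks, pure functions returning violation records:
label/definition cardinality (exactly one label, at most one primary
definition, obsolete stubs exempt); `replaced_by` integrity (undeclared
target ERROR, chain through another obsolete stub WARNING with the chain's
terminal id suggested, cycle ERROR, 20-hop cap); ssAO xref consistency
(a species-specific AO cross-referencing a merged namespace must hit an
obsoleted-and-replaced stub — anything else is an incomplete merge); and
orphans (non-obsolete classes with no `is_a`/`part_of` parents, or parked
directly under a configured root). ERROR blocks a release (non-zero CLI
exit), WARNING does not; the severity split is this package's choice. The
only automated repair offered is xref rewiring to the suggested terminal id.

## Synthetic fixtures

The generator emulates the *shape* of a historical merge input: a rooted
source DAG with seeded `is_a` backbone plus extra `part_of`/`develops_from`
axioms (mean axioms per class ≈ `axiom_density`, default 1.5), a target
containing one pre-existing class per mapped source class (sharing its
label, or — for a seeded fraction, default 0.2 — only a synonym), and a
valid mapping table. Planted facts (mapped pairs, orphans, classes with a
deliberately non-mirrored extra axiom) are returned as ground truth so
tests compare against data, not generator internals. Identical seeds give
byte-identical serialized files.

Two structural notes. First, a class attached directly below the root is
definitionally an orphan, and in a rooted ontology the first class below
the root has no other possible parent; the generator therefore requires at
least one planted orphan for any fixture of two or more classes (default 1)
and lets that orphan double as the trunk the anchored classes hang from.
Second, matched classes keep their backbone axioms, which the small target
does not mirror; merged targets therefore legitimately acquire structured
comments beyond the deliberately planted non-isomorphic axioms — ground
truth guarantees the planted ones, not an exact comment count.

What the fixtures do **not** emulate: realistic anatomical graph topology,
label polysemy across taxa, definition prose quality, or the curatorial
content of the historical ontologies. Passing tests demonstrate the
machinery (counting, minting, rewriting, conservation), not the biology.

## Problem sizes and numerics

The test and acceptance workloads use the historical input sizes directly
(3048/970 teleost-scale, 1595/789 amphibian-scale, 201/147 skeletal-scale)
because the whole pipeline is near-linear: a full 3048-class merge runs in
well under a second. Property suites use 100 random fixture specs (≤ 60
classes) and 200 random DAGs (≤ 12 nodes, against an exhaustive
path-enumeration oracle). All randomness is seeded; serialization is
canonical (sorted stanzas, fixed tag order, sorted list tags) so equal
ontologies produce identical bytes regardless of construction order.
Identifiers are opaque strings — no numeric padding equivalence — and
equivalence axioms are pair-normalized with the lexicographically smaller
CURIE as subject.

## Known limitations

No OWL/RDF serialization or DL reasoning; no GCIs (taxonomic equivalence
is sidecar data only); no import-chain resolution (the core/Ext split is a
file-pair convention); no taxon-constraint reasoning (taxon slims are
approximated by subset tags); candidate alignment is purely lexical, with
no embedding or structural matching; curatorial decisions (definition
broadening/narrowing, renaming ambiguous classes) are out of scope by
design.
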