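# anatomerge

Merging group-specific anatomy ontologies into one cross-species ontology.

Comparative studies — linking fish fin phenotypes to limb genes, or
comparing gene expression across vertebrates — need anatomical classes
that span taxa. Historically that meant folding several multi-species
anatomy ontologies (a teleost AO, an amphibian AO, a vertebrate skeletal
AO, and a homology-grouping vocabulary) into one unified target ontology,
while keeping every legacy identifier resolvable. `anatomerge` is a
toolkit for exactly that kind of ontology engineering, aimed at ontology
editors and release managers working with OBO flat files.

## What it does

Given source ontologies, a target ontology, and a curated table of
equivalence mappings (direct `A ≡ B`, or taxonomic
`A ⊓ ∃part_of.Taxon ≡ B`), the merge engine walks a decision tree over
every non-obsolete source class `A`:

- **mapped** → `A` is obsoleted with `replaced_by` its target equivalent
  `B`; `B` absorbs `A`'s label/synonyms (as synonyms), its definition (as
  an *external definition* annotation when the texts differ), its id (as
  an xref), and a structured comment for every axiom of `A` that `B`
  lacks — conservative transfer, never new logical axioms;
- **unmapped** → a new id is minted in a per-source ID space
  (`UBERON:2nnnnnn` for TAO, `3nnnnnn` for AAO, `40nnnnn` for VSAO,
  preserving the source number's tail, e.g. TAO:0001611 → UBERON:2001611),
  the class is copied verbatim into an extension (Ext) ontology, its
  axioms rewritten through the mapping (`X part_of TAO:0000621` becomes
  `X part_of UBERON:0006597`), and `A` is obsoleted with `replaced_by`
  the minted id.

Around the engine: lexical candidate alignment for curators, design-pattern
rewrites (joint flipping: `element overlaps joint` → `joint connected_to
element`; tooth attachment normalization to `attaches_to`), pre-reasoned
closure over `is_a`/`part_of`/`develops_from` by binary property
composition, subset-slim extraction with relation re-wiring, pairwise
homology export from ancestral-structure groupings (`homologous_to`), and
the release-gate QC checks (label cardinality, `replaced_by` chains,
cross-ontology xref consistency, orphan detection). A deterministic
fixture generator makes the whole pipeline testable without any downloads.
See `docs/methods.md` for the full model.

## Worked example

The quadrate micro-example from the library API:

```python
from anatomerge import run_merge, DEFAULT_RULES, Identifier
from anatomerge.fixtures import build_worked_examples
from anatomerge.obo import write_obo

source, target, entries = build_worked_examples()["migration_pair"]
result = run_merge([source], target, entries, DEFAULT_RULES)
print("merged:", result.report.n_merged, " minted:", result.report.n_minted)
for sid, rep in result.report.obsolescence_records:
    print(f"{sid.curie} -> replaced_by {rep.curie}")
print(write_obo(result.ext))
```

prints

```
merged: 1  minted: 1
TAO:0000621 -> replaced_by UBERON:0006597
TAO:0001611 -> replaced_by UBERON:2001611
format-version: 1.2

[Term]
id: UBERON:2001611
name: quadrate posterodorsolateral process
def: "Process on the posterodorsolateral region of the quadrate." []
xref: TAO:0001611
relationship: part_of UBERON:0006597
```

The teleost quadrate (TAO:0000621) had a curated equivalence to the target
quadrate bone, so it is merged and obsoleted; its posterodorsolateral
process had none, so UBERON:2001611 is minted in the Ext file with the
`part_of` axiom rewritten to point at the merged target class.
The same flow from the shell:

```
anatomerge fixture --classes 40 --matched 15 --seed 3 --out fx
anatomerge merge --source fx/tao.obo --target fx/target.obo \
                 --mapping fx/mapping.tsv --out run
anatomerge qc --input run/core.obo --input run/ext.obo \
              --input run/tao-obsolete.obo --out qc.tsv
```

The merge writes `core.obo`, `ext.obo`, per-source obsolete-stub files, a
per-class report, and a manifest:

```json
{
 "merged": 15,
 "minted": 25,
 "skipped_preobsolete": 0,
 "obsolescence_records": 40,
 "comments_added": 23,
 "axioms_rewritten": 41,
 "axioms_dropped": 0
}
```

15 of the 40 fixture classes had mappings and were merged; the other 25
were minted into Ext; all 40 left obsolescence records. `qc` exits 0 here
because a clean merge output contains no ERROR-level violations.

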