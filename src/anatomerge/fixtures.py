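"""Deterministic synthetic-ontology generator.

Produces source/target/mapping triples shaped like the historical
multi-species anatomy merges (thousands of source classes, a curated
subset with equivalence mappings to the target), plus the small worked
micro-examples used throughout the documentation.  Everything is seeded:
the same spec always yields byte-identical serialized files.  Ground
truth about planted facts (mapped pairs, orphans, non-isomorphic
classes) is returned as data so tests never re-derive it from generator
internals.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .align import MappingEntry
from .merge import DEFAULT_RULES, IDSpaceRule
from .model import (
    Axiom,
    ClassTerm,
    Definition,
    Identifier,
    Ontology,
    Synonym,
    is_a,
    relationship,
)
from .obo import write_mapping_table, write_obo

_ADJECTIVES = (
    "dorsal", "ventral", "anterior", "posterior", "lateral", "medial",
    "proximal", "distal", "superficial", "deep", "rostral", "caudal",
)
_NOUNS = (
    "process", "ridge", "foramen", "cartilage", "bone", "muscle",
    "ligament", "joint capsule", "tubercle", "fossa", "crest", "plate",
)


class InfeasibleSpecError(Exception):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Size and shape of one synthetic source/target/mapping triple."""

    n_source_classes: int
    n_matched: int
    source_prefix: str = "TAO"
    id_rule: Optional[IDSpaceRule] = None
    axiom_density: float = 1.5
    planted_orphans: int = 1
    planted_nonisomorphic: int = 1
    synonym_share_fraction: float = 0.2
    mapping_type: str = "direct"
    taxon: Optional[str] = None
    seed: int = 0

    def rule(self) -> IDSpaceRule:
        if self.id_rule is not None:
            return self.id_rule
        if self.source_prefix in DEFAULT_RULES:
            return DEFAULT_RULES[self.source_prefix]
        return IDSpaceRule(self.source_prefix, "9", 6)

    def validate(self) -> None:
        n = self.n_source_classes
        if min(n, self.n_matched, self.planted_orphans,
               self.planted_nonisomorphic) < 0:
            raise InfeasibleSpecError("counts must be non-negative")
        if self.n_matched > n:
            raise InfeasibleSpecError(
                f"n_matched ({self.n_matched}) > n_source_classes ({n})")
        if n == 0 and self.planted_orphans > 0:
            raise InfeasibleSpecError("cannot plant orphans in an empty source")
        if n >= 2 and self.planted_orphans < 1:
            raise InfeasibleSpecError(
                "at least one orphan is structurally required: the first "
                "class placed below the root has no other possible parent")
        if n >= 1 and self.planted_orphans > n - 1:
            raise InfeasibleSpecError("too many orphans for the class count")
        if self.planted_nonisomorphic > self.n_matched:
            raise InfeasibleSpecError(
                "cannot plant more non-isomorphic classes than matches")


@dataclass
class GroundTruth:
    """Machine-readable record of every fact the generator planted."""

    matched_pairs: list[tuple[Identifier, Identifier]] = field(
        default_factory=list)
    exact_label_pairs: list[tuple[Identifier, Identifier]] = field(
        default_factory=list)
    synonym_only_pairs: list[tuple[Identifier, Identifier]] = field(
        default_factory=list)
    orphan_ids: list[Identifier] = field(default_factory=list)
    root_ids: list[Identifier] = field(default_factory=list)
    nonisomorphic: list[tuple[Identifier, Axiom]] = field(default_factory=list)

    def to_json(self) -> str:
        def ax(a: Axiom) -> dict:
            return {"subject": a.subject.curie, "kind": a.kind.name,
                    "property": a.property, "object": a.object.curie}
        return json.dumps({
            "matched_pairs": [[s.curie, t.curie]
                              for s, t in self.matched_pairs],
            "exact_label_pairs": [[s.curie, t.curie]
                                  for s, t in self.exact_label_pairs],
            "synonym_only_pairs": [[s.curie, t.curie]
                                   for s, t in self.synonym_only_pairs],
            "orphan_ids": [i.curie for i in self.orphan_ids],
            "root_ids": [i.curie for i in self.root_ids],
            "nonisomorphic": [[s.curie, ax(a)] for s, a in self.nonisomorphic],
        }, indent=1)


def _label(rng: random.Random, index: int) -> str:
    return f"{rng.choice(_ADJECTIVES)} {rng.choice(_NOUNS)} {index}"


def generate_fixture(spec: FixtureSpec
                     ) -> tuple[Ontology, Ontology, list[MappingEntry],
                                GroundTruth]:
    """Build one deterministic (source, target, mapping, ground truth).

    The source is a rooted DAG: a root class, ``planted_orphans``
    classes parked directly below it (the first doubles as the trunk the
    rest of the ontology hangs from), and the remaining classes placed
    at depth >= 2 with seeded is_a parents plus extra part_of /
    develops_from axioms up to ``axiom_density``.  ``n_matched`` classes
    get mapping entries to distinct target classes sharing their label
    (or, for a seeded fraction, only a synonym).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    truth = GroundTruth()

    source = Ontology(header=[("format-version", "1.2"),
                              ("ontology", spec.source_prefix.lower())])
    target = Ontology(header=[("format-version", "1.2"),
                              ("ontology", "uberon")])

    target_root = Identifier("UBERON", "0000001")
    target.add_class(ClassTerm(
        id=target_root, label="anatomical entity",
        definition=Definition("The root of all anatomical structure.")))

    n = spec.n_source_classes
    if n == 0:
        return source, target, [], truth

    prefix = spec.source_prefix
    sids = [Identifier(prefix, str(i + 1).zfill(7)) for i in range(n)]
    root = sids[0]
    truth.root_ids = [root]
    source.add_class(ClassTerm(
        id=root, label=f"anatomical structure ({prefix})",
        definition=Definition(f"Root class of the {prefix} fixture.")))

    orphans = sids[1:1 + spec.planted_orphans]
    anchored = sids[1 + spec.planted_orphans:]
    trunk = orphans[0] if orphans else None

    # choose matched classes among the non-root classes (root last resort)
    pool = sids[1:]
    rng.shuffle(pool)
    matched = pool[:spec.n_matched]
    if spec.n_matched > len(pool):
        matched.append(root)
    matched_set = set(matched)

    # labels for the whole source, target mirrors for matched classes
    taxon_id = (Identifier.parse(spec.taxon) if spec.taxon
                else Identifier("NCBITaxon", "7776"))
    entries: list[MappingEntry] = []
    target_locals = iter(range(2, 2 + n + 5))
    for i, sid in enumerate(sids[1:], start=1):
        label = _label(rng, i)
        term = ClassTerm(id=sid, label=label,
                         definition=Definition(
                             f"The {label} of the organism body."))
        source.add_class(term)
        if sid in matched_set:
            tid = Identifier("UBERON", str(next(target_locals)).zfill(7))
            share_synonym = rng.random() < spec.synonym_share_fraction
            if share_synonym:
                tterm = ClassTerm(
                    id=tid, label=f"{label} structure",
                    definition=Definition(
                        f"The {label} of the organism body, vetted."),
                    synonyms=[Synonym(label, "EXACT")])
                truth.synonym_only_pairs.append((sid, tid))
            else:
                tterm = ClassTerm(
                    id=tid, label=label,
                    definition=Definition(
                        f"The {label} of the organism body, vetted."))
                truth.exact_label_pairs.append((sid, tid))
            target.add_class(tterm)
            target.add_axiom(is_a(tid, target_root))
            entries.append(MappingEntry(
                source_id=sid, target_id=tid,
                mapping_type=spec.mapping_type,
                taxon=taxon_id if spec.mapping_type == "taxonomic" else None,
                provenance="fixture"))
            truth.matched_pairs.append((sid, tid))

    if root in matched_set:
        tid = Identifier("UBERON", str(next(target_locals)).zfill(7))
        target.add_class(ClassTerm(
            id=tid, label=f"anatomical structure ({prefix})",
            definition=Definition(f"Root class of the {prefix} fixture, "
                                  "vetted.")))
        target.add_axiom(is_a(tid, target_root))
        entries.append(MappingEntry(
            source_id=root, target_id=tid, mapping_type=spec.mapping_type,
            taxon=taxon_id if spec.mapping_type == "taxonomic" else None,
            provenance="fixture"))
        truth.matched_pairs.append((root, tid))
        truth.exact_label_pairs.append((root, tid))

    # wiring: orphans sit directly below the root, everything else hangs
    # from the trunk at depth >= 2
    for oid in orphans:
        source.add_axiom(is_a(oid, root))
        truth.orphan_ids.append(oid)
    placed: list[Identifier] = [trunk] if trunk else []
    for sid in anchored:
        parent = rng.choice(placed)
        source.add_axiom(is_a(sid, parent))
        placed.append(sid)

    # extra relationship axioms up to the requested density
    extra_p = max(0.0, spec.axiom_density - 1.0)
    for sid in anchored:
        while rng.random() < extra_p and len(placed) > 1:
            obj = rng.choice(placed)
            if obj == sid:
                continue
            prop = rng.choice(("part_of", "part_of", "develops_from"))
            source.add_axiom(relationship(sid, prop, obj))
            extra_p /= 2  # geometric tail
        extra_p = max(0.0, spec.axiom_density - 1.0)

    # planted non-isomorphic matched classes: one extra relationship the
    # target side does not mirror
    noniso = rng.sample(sorted(matched_set, key=lambda i: i.curie),
                        spec.planted_nonisomorphic)
    for sid in noniso:
        candidates = [x for x in sids[1:] if x != sid]
        obj = rng.choice(candidates) if candidates else root
        ax = relationship(sid, "overlaps", obj)
        source.add_axiom(ax)
        truth.nonisomorphic.append((sid, ax))

    return source, target, entries, truth


def write_fixture(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Serialize a generated fixture to OBO/TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source, target, entries, truth = generate_fixture(spec)
    paths = {
        "source": out / f"{spec.source_prefix.lower()}.obo",
        "target": out / "target.obo",
        "mapping": out / "mapping.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    paths["source"].write_text(write_obo(source), encoding="utf-8")
    paths["target"].write_text(write_obo(target), encoding="utf-8")
    paths["mapping"].write_text(write_mapping_table(entries), encoding="utf-8")
    paths["ground_truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# worked micro-examples

def _term(curie: str, label: str, **kw) -> ClassTerm:
    return ClassTerm(id=Identifier.parse(curie), label=label, **kw)


def build_worked_examples() -> dict:
    """The documentation micro-fixtures.

    * ``joint_flip`` — skeletal elements with element->joint ``overlaps``
      axioms (quadrate / anguloarticular / metapterygoid and their
      joints), input for the joint-flip rewrite;
    * ``migration_pair`` — the quadrate posterodorsolateral process and
      its mapped parent quadrate, input for an ID-space migration;
    * ``masseter`` — the muscle property pattern (origin, insertion,
      innervation, function) exercising the object-property registry;
    * ``homology`` — the lung / swim bladder ancestral grouping.
    """
    # (a) joints prior to the flip
    joints = Ontology(header=[("format-version", "1.2")])
    joints.add_class(_term("TAO:0001247", "skeletal element"))
    for curie, label in [
        ("TAO:0000621", "quadrate"),
        ("TAO:0000217", "anguloarticular"),
        ("TAO:0000622", "metapterygoid"),
        ("TAO:0001637", "quadrate-anguloarticular joint"),
        ("TAO:0001638", "metapterygoid-quadrate joint"),
    ]:
        joints.add_class(_term(curie, label))
        joints.add_axiom(is_a(Identifier.parse(curie),
                              Identifier.parse("TAO:0001247")))
    quadrate = Identifier.parse("TAO:0000621")
    anguloarticular = Identifier.parse("TAO:0000217")
    metapterygoid = Identifier.parse("TAO:0000622")
    qaa_joint = Identifier.parse("TAO:0001637")
    mq_joint = Identifier.parse("TAO:0001638")
    joints.add_axiom(relationship(quadrate, "overlaps", qaa_joint))
    joints.add_axiom(relationship(anguloarticular, "overlaps", qaa_joint))
    joints.add_axiom(relationship(metapterygoid, "overlaps", mq_joint))
    joints.add_axiom(relationship(quadrate, "overlaps", mq_joint))

    # (b) migration pair: unmatched process, matched quadrate
    mig_source = Ontology(header=[("format-version", "1.2")])
    mig_source.add_class(_term(
        "TAO:0000621", "quadrate",
        definition=Definition("Endochondral bone that is the dorsal part "
                              "of the palatoquadrate arch.")))
    mig_source.add_class(_term(
        "TAO:0001611", "quadrate posterodorsolateral process",
        definition=Definition("Process on the posterodorsolateral region "
                              "of the quadrate.")))
    mig_source.add_axiom(relationship(
        Identifier.parse("TAO:0001611"), "part_of",
        Identifier.parse("TAO:0000621")))
    mig_target = Ontology(header=[("format-version", "1.2")])
    mig_target.add_class(_term(
        "UBERON:0006597", "quadrate bone",
        definition=Definition("Endochondral bone forming the jaw "
                              "articulation in non-mammalian vertebrates.")))
    mig_entries = [
        MappingEntry(source_id=Identifier.parse("TAO:0000621"),
                     target_id=Identifier.parse("UBERON:0006597"),
                     mapping_type="taxonomic",
                     taxon=Identifier.parse("NCBITaxon:32443"),
                     provenance="worked-example"),
    ]

    # (c) masseter muscle property pattern
    masseter = Ontology(header=[("format-version", "1.2")])
    m_id = Identifier.parse("UBERON:0001597")
    masseter.add_class(_term("UBERON:0001597", "masseter muscle"))
    for curie, label in [
        ("UBERON:0001684", "mandible"),
        ("UBERON:0002501", "zygomatic arch"),
        ("UBERON:0002397", "maxilla"),
        ("UBERON:0001567", "cheek"),
        ("UBERON:0018412", "masseteric nerve"),
    ]:
        masseter.add_class(_term(curie, label))
    for prop, obj in [
        ("capable_of_part_of", "GO:0071626"),   # mastication
        ("has_muscle_insertion", "UBERON:0001684"),
        ("has_muscle_origin", "UBERON:0002501"),
        ("has_muscle_origin", "UBERON:0002397"),
        ("part_of", "UBERON:0001567"),
        ("innervated_by", "UBERON:0018412"),
    ]:
        masseter.add_axiom(relationship(m_id, prop, Identifier.parse(obj)))

    # (d) homology grouping: the ancestral lung / swim bladder structure
    homology_groupings = [
        ("lung - swim bladder",
         [Identifier.parse("UBERON:0002048"),    # lung
          Identifier.parse("UBERON:0006860")]),  # swim bladder
    ]

    return {
        "joint_flip": joints,
        "migration_pair": (mig_source, mig_target, mig_entries),
        "masseter": masseter,
        "homology": homology_groupings,
    }


__all__ = [
    "FixtureSpec", "GroundTruth", "InfeasibleSpecError",
    "generate_fixture", "write_fixture", "build_worked_examples",
]
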