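"""Mapping-driven merge of source anatomy ontologies into a target.

The engine walks a decision tree over every non-obsolete source class:

* classes with a curated equivalence mapping are *merged* — the target
  class absorbs their synonyms, xrefs and external definitions, gains a
  structured comment for every source axiom it lacks, and the source
  class is obsoleted with ``replaced_by`` pointing at the target;
* classes without a mapping are *migrated* — a new identifier is minted
  in a per-source ID space (a fixed lead digit block plus the preserved
  tail of the source number), the class is copied verbatim into the
  extension (Ext) ontology, its axioms rewritten through the mapping,
  and the source class obsoleted with ``replaced_by`` the minted id;
* classes already obsolete before the run are skipped, their
  replaced_by chains preserved for downstream consistency checks.

Information is conservatively never discarded: axioms that cannot be
asserted on a merged target class (they may not hold across the wider
taxonomic range the target covers) become structured comments, and
axioms whose objects have no image under the mapping are reported as
drop records, never silently lost.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .align import MappingEntry, MappingViolation, validate_mappings
from .model import (
    Axiom,
    AxiomKind,
    ClassTerm,
    Definition,
    Identifier,
    Ontology,
    Synonym,
    relationship,
)

_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS.sub(" ", text.strip())


class MergeError(Exception):
    pass


class CollisionError(MergeError):
    pass


class IdSpaceExhaustedError(MergeError):
    pass


class MergeValidationError(MergeError):
    def __init__(self, violations):
        self.violations = violations
        super().__init__(
            f"{len(violations)} mapping violation(s); merge aborted before "
            "mutation: " + "; ".join(v.message for v in violations[:5]))


# ---------------------------------------------------------------------------
# ID minting

@dataclass(frozen=True)
class IDSpaceRule:
    """Rule for minting migrated identifiers for one source prefix.

    The minted local id is ``lead_digits`` followed by the final
    ``preserved_digits`` digits of the source local id, zero-padded —
    e.g. lead "2" with six preserved digits sends TAO:0001611 to
    UBERON:2001611.
    """

    source_prefix: str
    lead_digits: str
    preserved_digits: int
    target_prefix: str = "UBERON"
    local_width: int = 7

    def __post_init__(self) -> None:
        if len(self.lead_digits) + self.preserved_digits != self.local_width:
            raise MergeError(
                f"{self.source_prefix}: lead digits + preserved digits must "
                f"equal the local width ({self.local_width})")


#: The historical source ID spaces: TAO migrated into UBERON:2nnnnnn,
#: AAO into UBERON:3nnnnnn, VSAO into UBERON:40nnnnn.
DEFAULT_RULES = {
    "TAO": IDSpaceRule("TAO", "2", 6),
    "AAO": IDSpaceRule("AAO", "3", 6),
    "VSAO": IDSpaceRule("VSAO", "40", 5),
}


def mint_migrated_id(source_id: Identifier, rule: IDSpaceRule,
                     existing: set[Identifier]) -> Identifier:
    """Mint the migrated identifier for one source class."""
    if source_id.prefix != rule.source_prefix:
        raise MergeError(f"{source_id.curie} does not match rule prefix "
                         f"{rule.source_prefix}")
    if not source_id.local_id.isdigit():
        raise MergeError(f"{source_id.curie}: local id is not numeric")
    tail = source_id.local_id.zfill(rule.preserved_digits)[-rule.preserved_digits:]
    minted = Identifier(rule.target_prefix, rule.lead_digits + tail)
    if minted in existing:
        raise CollisionError(
            f"minted id {minted.curie} for {source_id.curie} already declared")
    return minted


@dataclass
class NovelIdAllocator:
    """Monotone allocator for brand-new classes (default UBERON:42nnnnn)."""

    space_lead: str = "42"
    next_counter: int = 1
    target_prefix: str = "UBERON"
    local_width: int = 7

    def mint(self, existing: set[Identifier]) -> Identifier:
        width = self.local_width - len(self.space_lead)
        while True:
            if self.next_counter >= 10 ** width:
                raise IdSpaceExhaustedError(
                    f"{self.target_prefix}:{self.space_lead}* space exhausted")
            cand = Identifier(self.target_prefix,
                              self.space_lead + str(self.next_counter).zfill(width))
            self.next_counter += 1
            if cand not in existing:
                return cand


def mint_novel_id(alloc: NovelIdAllocator,
                  existing: set[Identifier]) -> Identifier:
    return alloc.mint(existing)


# ---------------------------------------------------------------------------
# axiom translation

@dataclass(frozen=True)
class DropRecord:
    axiom: Axiom
    reason: str


def translate_axiom(ax: Axiom, mapping: dict[Identifier, Identifier]
                    ) -> Union[Axiom, DropRecord]:
    """Rewrite an axiom's subject and object through the id mapping.

    Identifiers without an image yield a :class:`DropRecord` instead of a
    silently broken axiom.
    """
    if ax.subject not in mapping:
        return DropRecord(ax, "UNMAPPED_SUBJECT")
    if ax.object not in mapping:
        return DropRecord(ax, "UNMAPPED_OBJECT")
    return Axiom(mapping[ax.subject], ax.kind, mapping[ax.object],
                 property=ax.property, annotations=ax.annotations)


def check_isomorphism(source_id: Identifier, target_id: Identifier,
                      mapping: dict[Identifier, Identifier],
                      source: Ontology, target: Ontology) -> list[Axiom]:
    """Translated source axioms absent from the target class.

    An empty list means the two classes are isomorphic under the
    mapping; anything returned is a candidate for a structured comment
    on the target (never for a logical axiom).  Objects without an image
    are kept verbatim — they can never be present on the target, so the
    information still surfaces.
    """
    target_keys = {ax.key() for ax in target.axioms_about(target_id)}
    missing = []
    for ax in source.axioms_about(source_id):
        translated = Axiom(target_id, ax.kind,
                           mapping.get(ax.object, ax.object),
                           property=ax.property)
        if translated.key() not in target_keys:
            missing.append(translated)
    return missing


# ---------------------------------------------------------------------------
# report

MERGED_INTO_EXISTING = "MERGED_INTO_EXISTING"
MINTED_NEW = "MINTED_NEW"
SKIPPED_PREOBSOLETE = "SKIPPED_PREOBSOLETE"


@dataclass(frozen=True)
class MergeOutcome:
    source_id: Identifier
    outcome: str
    result_id: Optional[Identifier]


@dataclass
class MergeReport:
    """Per-class ledger of one merge run."""

    outcomes: list[MergeOutcome] = field(default_factory=list)
    comments_added: list[tuple[Identifier, str]] = field(default_factory=list)
    synonyms_transferred: int = 0
    external_definitions_added: int = 0
    axioms_rewritten: int = 0
    axioms_dropped: list[DropRecord] = field(default_factory=list)
    obsolescence_records: list[tuple[Identifier, Identifier]] = field(
        default_factory=list)

    def n_with(self, outcome: str) -> int:
        return sum(1 for o in self.outcomes if o.outcome == outcome)

    @property
    def n_merged(self) -> int:
        return self.n_with(MERGED_INTO_EXISTING)

    @property
    def n_minted(self) -> int:
        return self.n_with(MINTED_NEW)

    @property
    def n_skipped(self) -> int:
        return self.n_with(SKIPPED_PREOBSOLETE)

    def to_tsv(self) -> str:
        rows = ["source_id\toutcome\tresult_id"]
        for o in sorted(self.outcomes, key=lambda o: o.source_id.curie):
            rows.append(f"{o.source_id.curie}\t{o.outcome}\t"
                        f"{o.result_id.curie if o.result_id else ''}")
        return "\n".join(rows) + "\n"


@dataclass
class MergeResult:
    core: Ontology
    ext: Ontology
    stubs: dict[str, Ontology]  # per source prefix
    report: MergeReport


# ---------------------------------------------------------------------------
# per-class operations

STRUCTURED_COMMENT_TEMPLATE = (
    "MERGE NOTE [{source}]: source asserts {subject} {property} {object}; "
    "not asserted here because it may not hold in the wider taxonomic "
    "context.")


def _label_of(ident: Identifier, *ontologies: Ontology) -> str:
    for onto in ontologies:
        term = onto.classes.get(ident)
        if term is not None and term.label:
            return term.label
    return ident.curie


def structured_comment(source_id: Identifier, missing: Axiom,
                       source: Ontology, target: Ontology) -> str:
    prop = "is_a" if missing.kind is AxiomKind.IS_A else missing.property
    return STRUCTURED_COMMENT_TEMPLATE.format(
        source=source_id.curie,
        subject=_label_of(missing.subject, target, source),
        property=prop,
        object=_label_of(missing.object, target, source))


def merge_matched(source_term: ClassTerm, target_term: ClassTerm,
                  mapping: dict[Identifier, Identifier],
                  source: Ontology, target: Ontology,
                  report: MergeReport) -> None:
    """Fold a mapped source class into its pre-existing target class.

    The target gains only annotation-level payload: structured comments
    for non-isomorphic axioms, the source definition as an external
    definition when it differs, the source label and synonyms as
    synonyms, and the source id as an xref.  No logical axiom is added.
    """
    if target_term.is_obsolete:
        raise MergeError(f"cannot merge {source_term.id.curie} into obsolete "
                         f"target {target_term.id.curie}")
    for missing in check_isomorphism(source_term.id, target_term.id,
                                     mapping, source, target):
        comment = structured_comment(source_term.id, missing, source, target)
        if comment not in target_term.comments:
            target_term.comments.append(comment)
            report.comments_added.append((target_term.id, comment))

    if source_term.definition is not None:
        src_text = _norm(source_term.definition.text)
        tgt_text = _norm(target_term.definition.text) \
            if target_term.definition else ""
        known = {_norm(d.text) for d in target_term.external_definitions}
        if src_text != tgt_text and src_text not in known:
            target_term.external_definitions.append(Definition(
                text=source_term.definition.text,
                provenance=source_term.definition.provenance
                + (source_term.id.curie,),
                is_external=True))
            report.external_definitions_added += 1

    present = {s.text.casefold() for s in target_term.synonyms}
    if target_term.label:
        present.add(target_term.label.casefold())
    incoming = []
    if source_term.label:
        incoming.append(Synonym(source_term.label, "EXACT",
                                xrefs=(source_term.id,)))
    for syn in source_term.synonyms:
        incoming.append(Synonym(syn.text, syn.scope, syn.type_tag,
                                xrefs=tuple(dict.fromkeys(
                                    syn.xrefs + (source_term.id,)))))
    for syn in incoming:
        if syn.text.casefold() not in present:
            target_term.synonyms.append(syn)
            present.add(syn.text.casefold())
            report.synonyms_transferred += 1

    if source_term.id not in target_term.xrefs:
        target_term.xrefs.append(source_term.id)


def migrate_unmatched(source_term: ClassTerm, minted_id: Identifier,
                      mapping: dict[Identifier, Identifier],
                      source: Ontology, ext: Ontology,
                      report: MergeReport) -> ClassTerm:
    """Copy an unmapped source class into Ext under its minted id.

    Label, definition, synonyms, xrefs and subsets are retained
    verbatim; axioms are rewritten through the mapping, and axioms whose
    objects have no image become drop records.
    """
    new = ClassTerm(
        id=minted_id,
        label=source_term.label,
        definition=source_term.definition,
        external_definitions=list(source_term.external_definitions),
        synonyms=list(source_term.synonyms),
        xrefs=list(source_term.xrefs) + [source_term.id],
        comments=list(source_term.comments),
        subsets=list(source_term.subsets),
        namespace_role="ext",
    )
    ext.add_class(new)
    for ax in source.axioms_about(source_term.id):
        out = translate_axiom(ax, mapping)
        if isinstance(out, DropRecord):
            report.axioms_dropped.append(out)
        else:
            ext.add_axiom(out)
            report.axioms_rewritten += 1
    return new


def obsolete_stub(source_term: ClassTerm,
                  replacement: Identifier) -> ClassTerm:
    """The obsolescence record left behind for a handled source class."""
    return ClassTerm(
        id=source_term.id,
        label=source_term.label,
        is_obsolete=True,
        replaced_by=[replacement],
    )


# ---------------------------------------------------------------------------
# whole-run driver

def run_merge(sources: Sequence[Ontology], target: Ontology,
              entries: Sequence[MappingEntry],
              rules: dict[str, IDSpaceRule],
              novel_allocator: Optional[NovelIdAllocator] = None
              ) -> MergeResult:
    """Execute the full merge decision tree over every source ontology.

    Sources are processed in the order given (historically TAO, AAO,
    VSAO, vHOG).  All mappings are validated and all ids minted before
    any mutation, so collisions or validation failures abort cleanly.
    The target is never structurally changed: the returned ``core`` is a
    copy augmented only with comments, synonyms, external definitions
    and xrefs; all minted classes live in the returned ``ext``.
    """
    violations: list[MappingViolation] = []
    union = Ontology()
    for src in sources:
        for term in src.terms():
            if term.id in union.classes:
                violations.append(MappingViolation(
                    "duplicate_source_id", term.id,
                    f"{term.id.curie} declared by more than one source"))
            else:
                union.classes[term.id] = term
    violations += validate_mappings(list(entries), union, target)
    if violations:
        raise MergeValidationError(violations)

    entry_map = {e.source_id: e.target_id for e in entries}
    source_prefixes = {i.prefix for src in sources for i in src.classes}

    existing: set[Identifier] = set(target.classes)
    for src in sources:
        existing |= set(src.classes)

    # plan: partition per source, mint every new id up front
    plan: list[tuple[Ontology, list[Identifier], list[Identifier],
                     list[Identifier]]] = []
    mapping: dict[Identifier, Identifier] = {}
    for src in sources:
        matched, unmatched, skipped = [], [], []
        for ident in sorted(src.classes, key=lambda i: i.curie):
            term = src.get(ident)
            if term.is_obsolete:
                skipped.append(ident)
            elif ident in entry_map:
                matched.append(ident)
                mapping[ident] = entry_map[ident]
            else:
                unmatched.append(ident)
        for ident in unmatched:
            rule = rules.get(ident.prefix)
            if rule is None:
                raise MergeError(f"no ID-space rule for prefix {ident.prefix}")
            minted = mint_migrated_id(ident, rule, existing)
            existing.add(minted)
            mapping[ident] = minted
        plan.append((src, matched, unmatched, skipped))

    # identity mapping for foreign objects (target ids, GO, taxa, ...)
    for src in sources:
        for ax in src.axioms:
            for ident in (ax.subject, ax.object):
                if ident.prefix not in source_prefixes and ident not in mapping:
                    mapping[ident] = ident

    core = target.copy()
    for term in core.terms():
        if not term.is_obsolete:
            term.namespace_role = "core"
    ext = Ontology(header=[("format-version", "1.2")],
                   registry=target.property_registry.copy())
    report = MergeReport()
    stubs: dict[str, Ontology] = {}

    for src, matched, unmatched, skipped in plan:
        for ident in matched + unmatched + skipped:
            if ident.prefix not in stubs:
                stubs[ident.prefix] = Ontology(
                    header=[("format-version", "1.2")])
        for ident in matched:
            term = src.get(ident)
            merge_matched(term, core.get(mapping[ident]), mapping,
                          src, core, report)
            stubs[ident.prefix].add_class(obsolete_stub(term, mapping[ident]))
            report.outcomes.append(
                MergeOutcome(ident, MERGED_INTO_EXISTING, mapping[ident]))
            report.obsolescence_records.append((ident, mapping[ident]))
        for ident in unmatched:
            term = src.get(ident)
            migrate_unmatched(term, mapping[ident], mapping, src, ext, report)
            stubs[ident.prefix].add_class(obsolete_stub(term, mapping[ident]))
            report.outcomes.append(
                MergeOutcome(ident, MINTED_NEW, mapping[ident]))
            report.obsolescence_records.append((ident, mapping[ident]))
        for ident in skipped:
            # keep the pre-existing obsolescence record and its chain
            term = src.get(ident)
            stubs[ident.prefix].add_class(ClassTerm(
                id=term.id, label=term.label, is_obsolete=True,
                replaced_by=list(term.replaced_by),
                consider=list(term.consider)))
            report.outcomes.append(
                MergeOutcome(ident, SKIPPED_PREOBSOLETE, None))
    return MergeResult(core=core, ext=ext, stubs=stubs, report=report)


# ---------------------------------------------------------------------------
# homology export

@dataclass(frozen=True)
class HomologyAssertion:
    """An unordered homology pair (normalized a < b by CURIE)."""

    entity_a: Identifier
    entity_b: Identifier
    relation: str = "homologous_to"
    evidence: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.entity_a == self.entity_b:
            raise MergeError("homology of an entity with itself")
        if self.entity_a.curie > self.entity_b.curie:
            raise MergeError("homology pair not normalized (a < b)")


def export_homology(groupings: Sequence[tuple[str, Sequence[Identifier]]],
                    evidence: str = "") -> list[HomologyAssertion]:
    """Expand homologous-structure groupings into pairwise assertions.

    Each grouping (e.g. the ancestral 'lung - swim bladder' structure)
    yields one assertion per unordered pair of distinct members.
    """
    out = []
    for label, members in groupings:
        distinct = sorted(set(members), key=lambda i: i.curie)
        if len(distinct) < 2:
            raise MergeError(
                f"homology grouping {label!r} needs >= 2 distinct members")
        for a, b in itertools.combinations(distinct, 2):
            out.append(HomologyAssertion(a, b, evidence=evidence,
                                         reference=label))
    return out


def homology_axioms(assertions: Sequence[HomologyAssertion]) -> list[Axiom]:
    return [relationship(a.entity_a, a.relation, a.entity_b)
            for a in assertions]


def write_homology_table(assertions: Sequence[HomologyAssertion]) -> str:
    rows = ["entity_a\tentity_b\trelation\tevidence\treference"]
    for a in assertions:
        rows.append(f"{a.entity_a.curie}\t{a.entity_b.curie}\t{a.relation}\t"
                    f"{a.evidence}\t{a.reference}")
    return "\n".join(rows) + "\n"


__all__ = [
    "IDSpaceRule", "NovelIdAllocator", "DEFAULT_RULES",
    "mint_migrated_id", "mint_novel_id",
    "translate_axiom", "check_isomorphism", "DropRecord",
    "merge_matched", "migrate_unmatched", "obsolete_stub", "run_merge",
    "MergeOutcome", "MergeReport", "MergeResult",
    "MERGED_INTO_EXISTING", "MINTED_NEW", "SKIPPED_PREOBSOLETE",
    "HomologyAssertion", "export_homology", "homology_axioms",
    "write_homology_table", "structured_comment",
    "MergeError", "CollisionError", "IdSpaceExhaustedError",
    "MergeValidationError",
]
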