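"""Design-pattern rewrites applied across the merged ontology.

Two documented patterns are mechanized here:

* **joint flip** — source ontologies modeled skeletal elements as
  ``overlaps`` their joints; the merged ontology defines joints by the
  elements they connect to, so every element/joint ``overlaps`` axiom is
  replaced by ``joint connected_to element``.  Joints are defined by
  connectivity because individual bones vary in connectivity across
  the vertebrates the merged ontology covers.
* **attachment normalization** — teeth (and other attached structures)
  were variably related to their supporting bones via ``part_of``,
  ``connected_to`` or ``overlaps``; all are rewritten to one uniform
  ``attaches_to`` so queries over dentition behave the same whether the
  teeth sit on a jaw or a pharyngeal bone.

Class filters are explicit (id lists or label predicates) — pattern
scope is a curatorial decision, never inferred.  Both rewrites are
idempotent and log every change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .model import Axiom, AxiomKind, ClassTerm, Identifier, Ontology, relationship

ClassFilter = Callable[[ClassTerm], bool]


@dataclass(frozen=True)
class RewriteRule:
    name: str
    action: str  # REVERSE_WITH(property) | REPLACE_PROPERTY(property)
    property: str


@dataclass(frozen=True)
class RewriteLogEntry:
    rule: str
    old: Axiom
    new: Axiom

    def as_row(self) -> str:
        def fmt(ax: Axiom) -> str:
            prop = "is_a" if ax.kind is AxiomKind.IS_A else ax.property
            return f"{ax.subject.curie} {prop} {ax.object.curie}"
        return f"{self.rule}\t{fmt(self.old)}\t{fmt(self.new)}"


def label_contains(fragment: str) -> ClassFilter:
    frag = fragment.casefold()
    return lambda term: bool(term.label) and frag in term.label.casefold()


def id_list(ids: Iterable[Identifier]) -> ClassFilter:
    idset = set(ids)
    return lambda term: term.id in idset


default_joint_filter = label_contains("joint")


def flip_joint_axioms(onto: Ontology,
                      joint_filter: Optional[ClassFilter] = None
                      ) -> tuple[Ontology, list[RewriteLogEntry]]:
    """Replace element/joint ``overlaps`` axioms with joint-side
    ``connected_to`` axioms.

    Both directions of ``overlaps`` are matched (the relation is
    symmetric in intent); axioms between two joints or two non-joints
    are untouched.  Returns a rewritten copy and the rewrite log.
    """
    joint_filter = joint_filter or default_joint_filter
    result = onto.copy()
    is_joint = {i: joint_filter(t) for i, t in result.classes.items()}
    log: list[RewriteLogEntry] = []
    existing = {ax.logical_key() for ax in result.axioms}

    for ax in onto.axioms:
        if ax.kind is not AxiomKind.RELATIONSHIP or ax.property != "overlaps":
            continue
        subj_joint = is_joint.get(ax.subject, False)
        obj_joint = is_joint.get(ax.object, False)
        if subj_joint == obj_joint:
            continue
        joint, element = ((ax.subject, ax.object) if subj_joint
                          else (ax.object, ax.subject))
        new = relationship(joint, "connected_to", element)
        # remove the overlaps axiom, keep the connected_to (dedup'd)
        kept = [a for a in result.axioms_about(ax.subject)
                if a.logical_key() != ax.logical_key()]
        result.remove_axioms_about(ax.subject)
        for a in kept:
            result.add_axiom(a)
        if new.logical_key() not in existing:
            result.add_axiom(new)
            existing.add(new.logical_key())
        log.append(RewriteLogEntry("joint_flip", ax, new))
    return result, log


def normalize_attachment(onto: Ontology, attached_filter: ClassFilter,
                         support_filter: ClassFilter
                         ) -> tuple[Ontology, list[RewriteLogEntry]]:
    """Rewrite attached-structure/support axioms to uniform ``attaches_to``.

    Axioms ``X part_of Y``, ``X connected_to Y`` and ``X overlaps Y``
    where X passes ``attached_filter`` (e.g. teeth) and Y passes
    ``support_filter`` (e.g. skeletal elements) become
    ``X attaches_to Y``.  Other partonomy is untouched.
    """
    result = onto.copy()
    attached = {i for i, t in result.classes.items() if attached_filter(t)}
    support = {i for i, t in result.classes.items() if support_filter(t)}
    log: list[RewriteLogEntry] = []

    rewritable = ("part_of", "connected_to", "overlaps")
    for subject in sorted(attached, key=lambda i: i.curie):
        axioms = result.axioms_about(subject)
        changed = False
        new_axioms = []
        seen = set()
        for ax in axioms:
            if (ax.kind is AxiomKind.RELATIONSHIP
                    and ax.property in rewritable and ax.object in support):
                new = relationship(subject, "attaches_to", ax.object)
                log.append(RewriteLogEntry("attachment_normalization", ax, new))
                ax = new
                changed = True
            if ax.logical_key() not in seen:
                seen.add(ax.logical_key())
                new_axioms.append(ax)
        if changed:
            result.remove_axioms_about(subject)
            for ax in new_axioms:
                result.add_axiom(ax)
    return result, log


def write_rewrite_log(log: list[RewriteLogEntry]) -> str:
    rows = ["rule\told_axiom\tnew_axiom"]
    rows += [e.as_row() for e in log]
    return "\n".join(rows) + "\n"


__all__ = [
    "RewriteRule", "RewriteLogEntry", "ClassFilter",
    "flip_joint_axioms", "normalize_attachment",
    "label_contains", "id_list", "default_joint_filter", "write_rewrite_log",
]
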