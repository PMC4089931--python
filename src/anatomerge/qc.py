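"""Release-gate validation and cross-ontology consistency checks.

These are the syntactic conditions checked on every commit of a merged
release: label/definition cardinality, integrity of obsolescence
replaced_by chains, cross-references from species-specific anatomy
ontologies (ssAOs, e.g. a zebrafish ontology) into merged source
namespaces, and orphan classes parked at the root.  ERRORs block a
release; WARNINGs do not.  Checks never mutate the ontology — an
optional repair mode applies suggested xref replacements only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import AxiomKind, ClassTerm, Identifier, Ontology

ERROR = "ERROR"
WARNING = "WARNING"

#: checks registered with this module
CHECK_IDS = ("labels_definitions", "replaced_by", "ssao_xrefs", "orphans")

#: replaced_by chains longer than this are treated as cycles
MAX_CHAIN_HOPS = 20


@dataclass(frozen=True)
class ViolationRecord:
    check_id: str
    subject: Identifier
    severity: str
    message: str
    suggested_fix: Optional[Identifier] = None

    def __post_init__(self) -> None:
        assert self.check_id in CHECK_IDS, self.check_id
        assert self.severity in (ERROR, WARNING), self.severity


def check_labels_definitions(onto: Ontology) -> list[ViolationRecord]:
    """Every non-obsolete class: exactly one label, at most one primary
    definition.  (Obsolete stubs are exempt from the label rule.)"""
    out = []
    for term in onto.terms():
        if not term.is_obsolete and not term.label:
            out.append(ViolationRecord(
                "labels_definitions", term.id, ERROR,
                f"{term.id.curie} has no label"))
        # the in-memory model holds one label/definition slot; duplicates
        # surface via pass-through tags from a parsed document
        extra_names = [v for t, v in term.pass_through if t == "name"]
        if extra_names:
            out.append(ViolationRecord(
                "labels_definitions", term.id, ERROR,
                f"{term.id.curie} has {1 + len(extra_names)} labels"))
        extra_defs = [v for t, v in term.pass_through if t == "def"]
        if extra_defs:
            out.append(ViolationRecord(
                "labels_definitions", term.id, ERROR,
                f"{term.id.curie} has more than one text definition"))
    return out


def _chain_terminal(start: Identifier, classes: dict[Identifier, ClassTerm]
                    ) -> tuple[Optional[Identifier], bool]:
    """Follow replaced_by links; returns (terminal id or None, cycled)."""
    seen = {start}
    current = start
    for _ in range(MAX_CHAIN_HOPS):
        term = classes.get(current)
        if term is None or not term.is_obsolete or not term.replaced_by:
            return current, False
        current = term.replaced_by[0]
        if current in seen:
            return None, True
        seen.add(current)
    return None, True


def check_replaced_by(ontos: Sequence[Ontology]) -> list[ViolationRecord]:
    """Obsolete classes must point at declared, live replacements.

    A replaced_by target that is itself an obsolete stub (a historical
    chain, e.g. a class first replaced in one source then migrated
    again) is a WARNING carrying the chain's terminal id as the
    suggested fix; a chain cycle is an ERROR.
    """
    classes: dict[Identifier, ClassTerm] = {}
    for onto in ontos:
        classes.update(onto.classes)
    out = []
    for term in classes.values():
        if not term.is_obsolete:
            continue
        for rep in term.replaced_by:
            target = classes.get(rep)
            if target is None:
                out.append(ViolationRecord(
                    "replaced_by", term.id, ERROR,
                    f"{term.id.curie} replaced_by undeclared {rep.curie}"))
            elif target.is_obsolete:
                terminal, cycled = _chain_terminal(rep, classes)
                if cycled:
                    out.append(ViolationRecord(
                        "replaced_by", term.id, ERROR,
                        f"{term.id.curie} replaced_by chain through "
                        f"{rep.curie} cycles"))
                else:
                    out.append(ViolationRecord(
                        "replaced_by", term.id, WARNING,
                        f"{term.id.curie} replaced_by obsolete {rep.curie}; "
                        f"chain terminates at {terminal.curie}",
                        suggested_fix=terminal))
    return out


def check_ssao_xrefs(ssao: Ontology, merged: Sequence[Ontology]
                     ) -> list[ViolationRecord]:
    """Cross-references from a species-specific AO into merged source
    namespaces must point at obsoleted-and-replaced classes.

    An xref to a source class that was never obsoleted means the merge
    is incomplete (ERROR); an xref to a replaced stub gets a WARNING
    with the terminal replacement id so the ssAO file can be rewired.
    """
    classes: dict[Identifier, ClassTerm] = {}
    for onto in merged:
        classes.update(onto.classes)
    merged_prefixes = {i.prefix for i in classes}
    out = []
    for term in ssao.terms():
        for xref in term.xrefs:
            if xref.prefix not in merged_prefixes:
                continue
            target = classes.get(xref)
            if target is None:
                out.append(ViolationRecord(
                    "ssao_xrefs", term.id, ERROR,
                    f"{term.id.curie} xref to unknown {xref.curie}"))
            elif not target.is_obsolete:
                out.append(ViolationRecord(
                    "ssao_xrefs", term.id, ERROR,
                    f"{term.id.curie} xref to {xref.curie}, which was never "
                    "obsoleted and replaced"))
            elif target.replaced_by:
                terminal, cycled = _chain_terminal(xref, classes)
                if cycled:
                    out.append(ViolationRecord(
                        "ssao_xrefs", term.id, ERROR,
                        f"{term.id.curie} xref to {xref.curie}: replacement "
                        "chain cycles"))
                else:
                    out.append(ViolationRecord(
                        "ssao_xrefs", term.id, WARNING,
                        f"{term.id.curie} xref to obsolete {xref.curie}; "
                        f"replace with {terminal.curie}",
                        suggested_fix=terminal))
            else:
                out.append(ViolationRecord(
                    "ssao_xrefs", term.id, ERROR,
                    f"{term.id.curie} xref to obsolete {xref.curie} with no "
                    "replacement"))
    return out


def repair_ssao_xrefs(ssao: Ontology,
                      violations: Iterable[ViolationRecord]) -> Ontology:
    """Apply suggested xref replacements (the only automated repair)."""
    fixed = ssao.copy()
    fixes: dict[tuple[Identifier, str], Identifier] = {}
    for v in violations:
        if v.check_id == "ssao_xrefs" and v.suggested_fix is not None:
            # message carries the offending xref; map by subject
            fixes[(v.subject, v.message.split(" xref to obsolete ")[1]
                   .split(";")[0])] = v.suggested_fix
    for term in fixed.terms():
        term.xrefs = [
            fixes.get((term.id, x.curie), x) for x in term.xrefs
        ]
    return fixed


def check_orphans(onto: Ontology, root_ids: Iterable[Identifier]
                  ) -> list[ViolationRecord]:
    """Classes placed only at/below a high-level root are flagged.

    A non-obsolete class with no is_a/part_of parents at all, or whose
    parents are all configured roots, is an orphan awaiting expert
    placement.  Root classes themselves are exempt.
    """
    roots = set(root_ids)
    out = []
    for term in onto.terms():
        if term.is_obsolete or term.id in roots:
            continue
        parents = {
            ax.object for ax in onto.axioms_about(term.id)
            if ax.kind is AxiomKind.IS_A
            or (ax.kind is AxiomKind.RELATIONSHIP and ax.property == "part_of")
        }
        if not parents:
            out.append(ViolationRecord(
                "orphans", term.id, WARNING,
                f"{term.id.curie} has no is_a/part_of parent"))
        elif parents <= roots:
            out.append(ViolationRecord(
                "orphans", term.id, WARNING,
                f"{term.id.curie} is placed only under high-level root(s) "
                + ", ".join(sorted(r.curie for r in parents))))
    return out


def run_all_checks(ontos: Sequence[Ontology],
                   ssao: Optional[Ontology] = None,
                   merged: Optional[Sequence[Ontology]] = None,
                   root_ids: Iterable[Identifier] = ()
                   ) -> list[ViolationRecord]:
    out: list[ViolationRecord] = []
    for onto in ontos:
        out.extend(check_labels_definitions(onto))
    out.extend(check_replaced_by(list(ontos) + list(merged or [])))
    if ssao is not None and merged:
        out.extend(check_ssao_xrefs(ssao, merged))
    roots = list(root_ids)
    if roots:
        for onto in ontos:
            out.extend(check_orphans(onto, roots))
    return out


def has_errors(violations: Iterable[ViolationRecord]) -> bool:
    return any(v.severity == ERROR for v in violations)


def write_violation_report(violations: Sequence[ViolationRecord]) -> str:
    rows = ["check_id\tsubject\tseverity\tmessage\tsuggested_fix"]
    for v in violations:
        fix = v.suggested_fix.curie if v.suggested_fix else ""
        rows.append(f"{v.check_id}\t{v.subject.curie}\t{v.severity}\t"
                    f"{v.message}\t{fix}")
    return "\n".join(rows) + "\n"


__all__ = [
    "ViolationRecord", "ERROR", "WARNING", "CHECK_IDS", "MAX_CHAIN_HOPS",
    "check_labels_definitions", "check_replaced_by", "check_ssao_xrefs",
    "check_orphans", "run_all_checks", "has_errors",
    "write_violation_report", "repair_ssao_xrefs",
]
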