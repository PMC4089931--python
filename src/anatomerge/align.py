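"""Lexical alignment between a source anatomy ontology and the merge target.

Candidate proposal mechanizes the manual-comparison phase of a
cross-species merge: classes with matching labels, synonyms, xrefs or
similar definitions are surfaced for curator review.  The merge itself
consumes only the curated mapping table — candidates are advisory.
Ambiguous labels (the same word naming unrelated structures in different
taxa) are deliberately NOT auto-resolved; exact-label candidates are
still emitted and left to curators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .model import ClassTerm, Identifier, Ontology

MAPPING_TYPES = ("direct", "taxonomic")


class MappingError(Exception):
    pass


@dataclass(frozen=True)
class MappingEntry:
    """A curated equivalence between a source class and a target class.

    ``direct`` entries assert plain equivalence (A == B); ``taxonomic``
    entries assert equivalence within a taxon (A and part_of some Taxon
    == B) and must carry the taxon CURIE.
    """

    source_id: Identifier
    target_id: Identifier
    mapping_type: str = "direct"
    taxon: Optional[Identifier] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.mapping_type not in MAPPING_TYPES:
            raise MappingError(f"unknown mapping_type {self.mapping_type!r}")
        if (self.taxon is not None) != (self.mapping_type == "taxonomic"):
            raise MappingError(
                f"{self.source_id.curie}: taxon must be present iff "
                "mapping_type is taxonomic")


@dataclass(frozen=True)
class CandidateMatch:
    source_id: Identifier
    target_id: Identifier
    score: float
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class MappingViolation:
    code: str
    source_id: Optional[Identifier]
    message: str


_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS.sub(" ", text.strip()).casefold()


def _tokens(text: str) -> frozenset[str]:
    return frozenset(re.findall(r"[a-z0-9]+", text.casefold()))


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


# evidence classes, strongest first; score 1.0 iff label_exact or xref
_EVIDENCE_SCORE = {
    "label_exact": 1.0,
    "xref": 1.0,
    "synonym_exact": 0.9,
    "definition_similarity": 0.8,
}


def _lexemes(term: ClassTerm) -> set[str]:
    names = set()
    if term.label:
        names.add(_norm(term.label))
    names.update(_norm(s.text) for s in term.synonyms)
    return names


def propose_candidates(source: Ontology, target: Ontology,
                       definition_threshold: float = 0.5
                       ) -> list[CandidateMatch]:
    """Score target classes as merge candidates for each source class.

    Label/synonym comparison is case-insensitive after whitespace
    normalization; definition similarity is token Jaccard against the
    given threshold.  Candidates are sorted by (source id, score
    descending, target id ascending).
    """
    # index target lexemes once
    by_label: dict[str, list[ClassTerm]] = {}
    by_lexeme: dict[str, list[ClassTerm]] = {}
    for t in target.terms():
        if t.is_obsolete:
            continue
        if t.label:
            by_label.setdefault(_norm(t.label), []).append(t)
        for lx in _lexemes(t):
            by_lexeme.setdefault(lx, []).append(t)

    target_ids = set(target.classes)
    target_def_tokens = [
        (t.id, _tokens(t.definition.text))
        for t in target.terms()
        if not t.is_obsolete and t.definition is not None
    ]
    candidates: list[CandidateMatch] = []
    for s in source.terms():
        if s.is_obsolete:
            continue
        evidence: dict[Identifier, set[str]] = {}
        label = _norm(s.label) if s.label else None
        if label:
            for t in by_label.get(label, []):
                evidence.setdefault(t.id, set()).add("label_exact")
        for lx in _lexemes(s):
            for t in by_lexeme.get(lx, []):
                ev = evidence.setdefault(t.id, set())
                if not (label and lx == label and _norm(t.label or "") == lx):
                    ev.add("synonym_exact")
        for x in s.xrefs:
            if x in target_ids and not target.get(x).is_obsolete:
                evidence.setdefault(x, set()).add("xref")
        if s.definition is not None:
            stoks = _tokens(s.definition.text)
            for tid, ttoks in target_def_tokens:
                if _jaccard(stoks, ttoks) >= definition_threshold:
                    evidence.setdefault(tid, set()).add("definition_similarity")
        for tid, evs in evidence.items():
            score = max(_EVIDENCE_SCORE[e] for e in evs)
            candidates.append(CandidateMatch(
                source_id=s.id, target_id=tid, score=score,
                evidence=tuple(sorted(evs))))
    candidates.sort(key=lambda c: (c.source_id.curie, -c.score,
                                   c.target_id.curie))
    return candidates


def validate_mappings(entries: list[MappingEntry], source: Ontology,
                      target: Ontology) -> list[MappingViolation]:
    """Pre-merge sanity checks on a curated mapping table.

    Violations are data, not exceptions: unknown ids, one source mapped
    to several targets, obsolete targets.  (Missing taxon on a taxonomic
    entry is rejected at construction time by :class:`MappingEntry`.)
    """
    out: list[MappingViolation] = []
    seen_targets: dict[Identifier, set[Identifier]] = {}
    for e in entries:
        if e.source_id not in source:
            out.append(MappingViolation(
                "unknown_source", e.source_id,
                f"{e.source_id.curie} not declared in source ontology"))
        if e.target_id not in target:
            out.append(MappingViolation(
                "unknown_target", e.source_id,
                f"{e.target_id.curie} not declared in target ontology"))
        elif target.get(e.target_id).is_obsolete:
            out.append(MappingViolation(
                "obsolete_target", e.source_id,
                f"{e.source_id.curie} maps to obsolete {e.target_id.curie}"))
        seen_targets.setdefault(e.source_id, set()).add(e.target_id)
    for sid, tids in seen_targets.items():
        if len(tids) > 1:
            out.append(MappingViolation(
                "multi_mapping", sid,
                f"{sid.curie} maps to {len(tids)} distinct targets: "
                + ", ".join(sorted(t.curie for t in tids))))
    return out


def partition_source_classes(source: Ontology, entries: list[MappingEntry]
                             ) -> tuple[list[Identifier], list[Identifier]]:
    """Split non-obsolete source classes into (matched, unmatched).

    The split is exhaustive and disjoint; matched classes will be merged
    into their pre-existing target class, unmatched classes will be
    migrated with a freshly minted identifier.
    """
    mapped = {e.source_id for e in entries}
    matched, unmatched = [], []
    for ident in sorted(source.nonobsolete_ids(), key=lambda i: i.curie):
        (matched if ident in mapped else unmatched).append(ident)
    return matched, unmatched


def write_candidate_report(candidates: list[CandidateMatch]) -> str:
    rows = ["source_id\ttarget_id\tscore\tevidence"]
    for c in candidates:
        rows.append(f"{c.source_id.curie}\t{c.target_id.curie}\t"
                    f"{c.score:g}\t{','.join(c.evidence)}")
    return "\n".join(rows) + "\n"


__all__ = [
    "MappingEntry", "CandidateMatch", "MappingViolation", "MappingError",
    "propose_candidates", "validate_mappings", "partition_source_classes",
    "write_candidate_report", "MAPPING_TYPES",
]
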