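"""Pre-reasoned relation closure and subset (slim) extraction.

Release consumers without a reasoner get "simple" files in which the
entailed ``is_a`` / ``part_of`` / ``develops_from`` edges are already
materialized.  Entailment here is binary composition over a small
property table (e.g. ``is_a o part_of -> part_of``), iterated to a
least fixed point.  Slims keep only the classes carrying a subset tag
and re-wire relations through the removed classes, dropping edges that
are entailed by the kept ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

import copy as _copy

from .model import AxiomKind, ClassTerm, Identifier, Ontology, is_a, relationship

#: a typed edge: (subject, property, object); property "is_a" stands for
#: the subclass axiom kind.
Edge = tuple[Identifier, str, Identifier]

IS_A = "is_a"


def _default_table() -> dict[tuple[str, str], str]:
    table = {(IS_A, IS_A): IS_A}
    for prop in ("part_of", "develops_from"):
        table[(prop, prop)] = prop
        table[(IS_A, prop)] = prop
        table[(prop, IS_A)] = prop
    return table


@dataclass
class CompositionTable:
    """Binary property-composition rules for pre-reasoning.

    The default covers the three release properties: both composition
    orders of ``is_a`` with a transitive property yield that property.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=_default_table)

    @property
    def properties(self) -> set[str]:
        out = set()
        for (p, q), r in self.entries.items():
            out |= {p, q, r}
        return out

    def compose(self, p: str, q: str) -> Optional[str]:
        return self.entries.get((p, q))


@dataclass
class ClosureResult:
    edges: set[Edge]
    warnings: list[str] = field(default_factory=list)


def _asserted_edges(onto: Ontology, props: set[str]) -> set[Edge]:
    edges: set[Edge] = set()
    for ax in onto.axioms:
        subj = onto.classes.get(ax.subject)
        if subj is not None and subj.is_obsolete:
            continue
        if ax.kind is AxiomKind.IS_A:
            edges.add((ax.subject, IS_A, ax.object))
        elif ax.kind is AxiomKind.RELATIONSHIP and ax.property in props:
            edges.add((ax.subject, ax.property, ax.object))
    return edges


def _is_a_cycles(edges: set[Edge]) -> list[list[Identifier]]:
    g = nx.DiGraph((s, o) for s, p, o in edges if p == IS_A)
    return [sorted(c, key=lambda i: i.curie)
            for c in nx.strongly_connected_components(g) if len(c) > 1]


def close_edges(edges: set[Edge], table: CompositionTable) -> set[Edge]:
    """Least fixed point of edge composition under the table
    (semi-naive iteration: only frontier edges are re-composed)."""
    closed = set(edges)
    by_subject: dict[Identifier, set[tuple[str, Identifier]]] = {}
    by_object: dict[Identifier, set[tuple[Identifier, str]]] = {}
    for s, p, o in closed:
        by_subject.setdefault(s, set()).add((p, o))
        by_object.setdefault(o, set()).add((s, p))

    frontier = set(closed)
    while frontier:
        new: set[Edge] = set()
        for s, p, o in frontier:
            for q, o2 in by_subject.get(o, ()):
                r = table.compose(p, q)
                if r is not None and (s, r, o2) not in closed:
                    new.add((s, r, o2))
            for s2, q in by_object.get(s, ()):
                r = table.compose(q, p)
                if r is not None and (s2, r, o) not in closed:
                    new.add((s2, r, o))
        closed |= new
        for s, p, o in new:
            by_subject.setdefault(s, set()).add((p, o))
            by_object.setdefault(o, set()).add((s, p))
        frontier = new
    return closed


def relation_closure(onto: Ontology,
                     table: Optional[CompositionTable] = None
                     ) -> ClosureResult:
    """Materialize every entailed edge over the table's properties.

    Asserted edges are always included.  ``is_a`` cycles are legal but
    reported as warnings listing the cycle members.
    """
    table = table or CompositionTable()
    asserted = _asserted_edges(onto, table.properties)
    warnings = [
        "is_a cycle: " + ", ".join(i.curie for i in cycle)
        for cycle in _is_a_cycles(asserted)
    ]
    return ClosureResult(edges=close_edges(asserted, table), warnings=warnings)


# ---------------------------------------------------------------------------
# slims

class SlimError(Exception):
    pass


def minimal_edges(edges: set[Edge], table: CompositionTable) -> set[Edge]:
    """Drop every edge entailed by composing two other edges of the set.

    The input must be composition-closed over its own nodes; then any
    longer derivation implies a two-step one, so the two-step test is
    complete.  When an ``is_a`` and a composite edge between the same
    pair are both entailed, the ``is_a`` reading is kept.
    """
    by_subject: dict[Identifier, set[tuple[str, Identifier]]] = {}
    for s, p, o in edges:
        by_subject.setdefault(s, set()).add((p, o))

    def redundant(edge: Edge) -> bool:
        s, p, o = edge
        for q, mid in by_subject.get(s, ()):
            if mid == o or mid == s:
                continue
            for r, o2 in by_subject.get(mid, ()):
                if o2 == o and table.compose(q, r) == p:
                    return True
        return False

    # two-step redundancy cannot involve a parallel edge over the same
    # pair, so parallel is_a/part_of edges both survive; when a composite
    # property and is_a are entailed between the same pair the is_a edge
    # is always the one retained by the check above.
    return {e for e in edges if not redundant(e)}


def extract_slim(onto: Ontology, subset_tag: str,
                 closure: Optional[ClosureResult] = None,
                 table: Optional[CompositionTable] = None,
                 minimal: bool = True) -> tuple[Ontology, list[str]]:
    """Reduce the ontology to the classes carrying ``subset_tag``.

    Relations are re-wired through removed classes using the closure;
    with ``minimal=True`` (the default) redundant entailed edges are
    dropped, otherwise every closure edge between kept classes is
    emitted.  Obsolete tagged classes are excluded with a warning.
    """
    table = table or CompositionTable()
    if closure is None:
        closure = relation_closure(onto, table)
    warnings = list(closure.warnings)

    tagged, skipped = [], []
    for term in onto.terms():
        if subset_tag in term.subsets:
            (skipped if term.is_obsolete else tagged).append(term.id)
    if not tagged and not skipped:
        raise SlimError(f"no class carries subset tag {subset_tag!r}")
    for ident in skipped:
        warnings.append(f"obsolete class {ident.curie} carries tag "
                        f"{subset_tag!r}; excluded from slim")

    keep = set(tagged)
    kept_edges = {(s, p, o) for s, p, o in closure.edges
                  if s in keep and o in keep and s != o}
    if minimal:
        kept_edges = minimal_edges(kept_edges, table)

    slim = Ontology(header=[("format-version", "1.2"),
                            ("subsetdef", subset_tag)],
                    registry=onto.property_registry.copy())
    for ident in sorted(keep, key=lambda i: i.curie):
        src = onto.get(ident)
        slim.add_class(ClassTerm(
            id=src.id, label=src.label, definition=src.definition,
            synonyms=list(src.synonyms), xrefs=list(src.xrefs),
            subsets=list(src.subsets)))
    for s, p, o in sorted(kept_edges,
                          key=lambda e: (e[0].curie, e[1], e[2].curie)):
        slim.add_axiom(is_a(s, o) if p == IS_A else relationship(s, p, o))
    return slim, warnings


def closure_ontology(onto: Ontology,
                     table: Optional[CompositionTable] = None
                     ) -> tuple[Ontology, list[str]]:
    """The pre-reasoned 'simple' product: same classes, materialized
    is_a/part_of/develops_from edges only."""
    table = table or CompositionTable()
    result = relation_closure(onto, table)
    out = Ontology(header=list(onto.header),
                   registry=onto.property_registry.copy())
    for ident in sorted(onto.classes, key=lambda i: i.curie):
        out.add_class(_copy.deepcopy(onto.get(ident)))
    for s, p, o in sorted(result.edges,
                          key=lambda e: (e[0].curie, e[1], e[2].curie)):
        subj = out.classes.get(s)
        if subj is not None and subj.is_obsolete:
            continue
        if s == o:
            continue
        out.add_axiom(is_a(s, o) if p == IS_A else relationship(s, p, o))
    return out, result.warnings


__all__ = [
    "CompositionTable", "ClosureResult", "Edge", "IS_A",
    "relation_closure", "close_edges", "minimal_edges", "extract_slim",
    "closure_ontology", "SlimError",
]
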