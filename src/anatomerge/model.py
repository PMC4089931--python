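"""In-memory model for OBO-style anatomy ontologies.

The model is deliberately small: named classes, three axiom kinds
(subclass, existential relationship, named-class equivalence), and a
registry of object properties.  Anonymous class expressions beyond a
single existential restriction are out of scope; taxonomic equivalence
(``A and part_of some Taxon EquivalentTo B``) is carried in the sidecar
mapping table, not as an in-memory axiom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class OntologyError(Exception):
    """Base class for model-level errors."""


class DuplicateIdError(OntologyError):
    pass


class InvalidTermError(OntologyError):
    pass


class InvalidAxiomError(OntologyError):
    pass


class UnknownPropertyError(OntologyError):
    pass


@dataclass(frozen=True, order=True)
class Identifier:
    """A compact identifier (CURIE) of the form ``PREFIX:LOCALID``.

    Identifiers are opaque strings compared case-sensitively; no numeric
    padding equivalence is applied (``TAO:0000621 != TAO:621``).
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not self.local_id:
            raise InvalidTermError(
                f"identifier needs non-empty prefix and local id: "
                f"{self.prefix!r}:{self.local_id!r}"
            )

    @classmethod
    def parse(cls, curie: str) -> "Identifier":
        prefix, sep, local = curie.strip().partition(":")
        if not sep:
            raise InvalidTermError(f"not a CURIE (missing colon): {curie!r}")
        return cls(prefix, local)

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


SYNONYM_SCOPES = ("EXACT", "NARROW", "BROAD", "RELATED")


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "EXACT"
    type_tag: Optional[str] = None
    xrefs: tuple[Identifier, ...] = ()

    def __post_init__(self) -> None:
        if self.scope not in SYNONYM_SCOPES:
            raise InvalidTermError(f"bad synonym scope {self.scope!r}")
        if not self.text:
            raise InvalidTermError("empty synonym text")


@dataclass(frozen=True)
class Definition:
    """A textual definition with provenance.

    ``is_external`` marks a definition carried over from a merged source
    class as an annotation rather than as the class's primary definition.
    """

    text: str
    provenance: tuple[str, ...] = ()
    is_external: bool = False


class AxiomKind(enum.IntEnum):
    # integer order doubles as the deterministic sort order
    IS_A = 0
    RELATIONSHIP = 1
    EQUIVALENCE = 2


@dataclass(frozen=True)
class Axiom:
    """A subclass, existential-relationship or equivalence assertion.

    RELATIONSHIP always means the existential form
    ``subject subClassOf property some object``; OWL ``some`` statements
    and OBO ``relationship:`` tags are unified under this one kind.
    """

    subject: Identifier
    kind: AxiomKind
    object: Identifier
    property: Optional[str] = None
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind is AxiomKind.RELATIONSHIP:
            if not self.property:
                raise InvalidAxiomError("RELATIONSHIP axiom requires a property")
        elif self.property is not None:
            raise InvalidAxiomError(f"{self.kind.name} axiom carries no property")

    def key(self) -> tuple:
        """Sort/identity key ignoring annotations."""
        return (int(self.kind), self.property or "", self.object.curie)

    def logical_key(self) -> tuple:
        return (self.subject.curie, int(self.kind), self.property or "",
                self.object.curie)


def is_a(subject: Identifier, obj: Identifier) -> Axiom:
    return Axiom(subject, AxiomKind.IS_A, obj)


def relationship(subject: Identifier, prop: str, obj: Identifier) -> Axiom:
    return Axiom(subject, AxiomKind.RELATIONSHIP, obj, property=prop)


def equivalence(a: Identifier, b: Identifier) -> Axiom:
    """Equivalence between named classes, pair-normalized so the
    lexicographically smaller CURIE is the subject (deterministic set
    comparison)."""
    if a == b:
        raise InvalidAxiomError("equivalence of a class with itself")
    lo, hi = sorted((a, b), key=lambda i: i.curie)
    return Axiom(lo, AxiomKind.EQUIVALENCE, hi)


@dataclass
class ClassTerm:
    """One ontology class with its lexical and administrative payload."""

    id: Identifier
    label: Optional[str] = None
    definition: Optional[Definition] = None
    external_definitions: list[Definition] = field(default_factory=list)
    synonyms: list[Synonym] = field(default_factory=list)
    xrefs: list[Identifier] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)
    subsets: list[str] = field(default_factory=list)
    namespace_role: str = "source"  # core | ext | source
    is_obsolete: bool = False
    replaced_by: list[Identifier] = field(default_factory=list)
    consider: list[Identifier] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    pass_through: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.is_obsolete:
            if not self.label:
                raise InvalidTermError(f"{self.id}: non-obsolete class needs a label")
            if self.replaced_by or self.consider:
                raise InvalidTermError(
                    f"{self.id}: replaced_by/consider on a non-obsolete class")
        if self.definition is not None and self.definition.is_external:
            raise InvalidTermError(
                f"{self.id}: primary definition flagged external")
        for d in self.external_definitions:
            if not d.is_external:
                raise InvalidTermError(
                    f"{self.id}: external_definitions entry not flagged external")


@dataclass(frozen=True)
class PropertyInfo:
    name: str
    transitive: bool = False
    symmetric: bool = False
    inverse: Optional[str] = None


#: Object properties the toolkit knows out of the box.  ``homologous_to``
#: is symmetric; ``part_of`` / ``develops_from`` / ``transformation_of``
#: are transitive.
DEFAULT_PROPERTIES = (
    PropertyInfo("part_of", transitive=True),
    PropertyInfo("overlaps", symmetric=True),
    PropertyInfo("connected_to", symmetric=True),
    PropertyInfo("attaches_to"),
    PropertyInfo("develops_from", transitive=True),
    PropertyInfo("transformation_of", transitive=True),
    PropertyInfo("immediate_transformation_of"),
    PropertyInfo("homologous_to", symmetric=True),
    PropertyInfo("innervated_by"),
    PropertyInfo("has_muscle_insertion"),
    PropertyInfo("has_muscle_origin"),
    PropertyInfo("capable_of_part_of"),
)


class ObjectPropertyRegistry:
    def __init__(self, properties: Iterable[PropertyInfo] = DEFAULT_PROPERTIES):
        self._props: dict[str, PropertyInfo] = {p.name: p for p in properties}

    def __contains__(self, name: str) -> bool:
        return name in self._props

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._props))

    def get(self, name: str) -> PropertyInfo:
        try:
            return self._props[name]
        except KeyError:
            raise UnknownPropertyError(name) from None

    def register(self, info: PropertyInfo) -> None:
        self._props[info.name] = info

    def ensure(self, name: str) -> None:
        """Auto-register an unknown property with default flags."""
        if name not in self._props:
            self._props[name] = PropertyInfo(name)

    def copy(self) -> "ObjectPropertyRegistry":
        return ObjectPropertyRegistry(self._props.values())


class Ontology:
    """A set of classes plus an axiom list and a property registry.

    Class-level invariants are enforced at mutation time (``add_class`` /
    ``add_axiom``), never deferred to serialization.
    """

    def __init__(self, header: Optional[list[tuple[str, str]]] = None,
                 registry: Optional[ObjectPropertyRegistry] = None):
        self.header: list[tuple[str, str]] = list(header or [])
        self.classes: dict[Identifier, ClassTerm] = {}
        self.property_registry = registry or ObjectPropertyRegistry()
        self._axioms: list[Axiom] = []
        self._by_subject: dict[Identifier, list[Axiom]] = {}

    # -- classes ---------------------------------------------------------
    def add_class(self, term: ClassTerm) -> "Ontology":
        if term.id in self.classes:
            raise DuplicateIdError(term.id.curie)
        term.validate()
        self.classes[term.id] = term
        return self

    def get(self, ident: Identifier) -> ClassTerm:
        return self.classes[ident]

    def __contains__(self, ident: Identifier) -> bool:
        return ident in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def terms(self) -> Iterator[ClassTerm]:
        return iter(self.classes.values())

    def nonobsolete_ids(self) -> list[Identifier]:
        return [i for i, t in self.classes.items() if not t.is_obsolete]

    # -- axioms ----------------------------------------------------------
    @property
    def axioms(self) -> list[Axiom]:
        return list(self._axioms)

    def add_axiom(self, ax: Axiom) -> "Ontology":
        if ax.kind is AxiomKind.RELATIONSHIP:
            self.property_registry.ensure(ax.property)  # warning-free auto-reg
        subj = self.classes.get(ax.subject)
        if subj is not None and subj.is_obsolete:
            raise InvalidAxiomError(
                f"axiom with obsolete subject {ax.subject.curie}")
        self._axioms.append(ax)
        self._by_subject.setdefault(ax.subject, []).append(ax)
        return self

    def axioms_about(self, ident: Identifier) -> list[Axiom]:
        """All axioms with the given subject, ordered (kind, property, object)."""
        return sorted(self._by_subject.get(ident, []), key=Axiom.key)

    def remove_axioms_about(self, ident: Identifier) -> list[Axiom]:
        removed = self._by_subject.pop(ident, [])
        if removed:
            gone = set(map(id, removed))
            self._axioms = [a for a in self._axioms if id(a) not in gone]
        return removed

    # -- validation ------------------------------------------------------
    def own_prefixes(self) -> set[str]:
        return {i.prefix for i in self.classes}

    def validate_references(self, external: Optional[set[Identifier]] = None
                            ) -> list[str]:
        """Check that axiom subjects/objects using a declared prefix
        resolve to declared classes (or to the supplied external set)."""
        external = external or set()
        prefixes = self.own_prefixes()
        problems = []
        for ax in self._axioms:
            for ident in (ax.subject, ax.object):
                if (ident.prefix in prefixes and ident not in self.classes
                        and ident not in external):
                    problems.append(
                        f"dangling reference {ident.curie} in axiom "
                        f"{ax.subject.curie} {ax.kind.name} {ax.object.curie}")
        return problems

    def copy(self) -> "Ontology":
        import copy as _copy

        clone = Ontology(header=list(self.header),
                         registry=self.property_registry.copy())
        clone.classes = {i: _copy.deepcopy(t) for i, t in self.classes.items()}
        clone._axioms = list(self._axioms)
        clone._by_subject = {k: list(v) for k, v in self._by_subject.items()}
        return clone


__all__ = [
    "Identifier", "Synonym", "Definition", "ClassTerm", "Axiom", "AxiomKind",
    "Ontology", "ObjectPropertyRegistry", "PropertyInfo", "DEFAULT_PROPERTIES",
    "is_a", "relationship", "equivalence",
    "OntologyError", "DuplicateIdError", "InvalidTermError",
    "InvalidAxiomError", "UnknownPropertyError", "SYNONYM_SCOPES",
]
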