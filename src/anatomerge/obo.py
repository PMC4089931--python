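"""Reader/writer for the OBO flat-file dialect the toolkit consumes and
produces, plus the tab-separated mapping-table sidecar.

The supported tag subset is: id, name, def, synonym, xref, is_a,
relationship, comment, subset, property_value, is_obsolete, replaced_by,
consider.  Unknown tags are preserved as opaque pass-through lines.
Serialization is canonical — stanzas sorted by id, tags in a fixed order,
list-valued tags sorted — so identical ontologies always produce
byte-identical files regardless of insertion order.  Taxonomic
equivalence is not expressible in this subset and lives only in the
mapping table.
"""

from __future__ import annotations

import warnings
from typing import Iterable, TextIO, Union

from .model import (
    Axiom,
    AxiomKind,
    ClassTerm,
    Definition,
    Identifier,
    InvalidAxiomError,
    Ontology,
    Synonym,
    is_a,
    relationship,
)

#: canonical tag order inside a [Term] stanza (stable diffs for releases)
TAG_ORDER = ("id", "name", "def", "comment", "subset", "synonym", "xref",
             "property_value", "is_a", "relationship", "is_obsolete",
             "replaced_by", "consider")

EXTERNAL_DEFINITION_PROP = "external_definition"
PROVENANCE_PROP = "provenance"


class OboParseError(Exception):
    pass


class UnserializableAxiomError(Exception):
    pass


# ---------------------------------------------------------------------------
# parsing helpers

def _strip_trailing_comment(value: str) -> str:
    """Drop an OBO trailing ``! label`` comment (outside quotes)."""
    in_quote = False
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\":
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        elif c == "!" and not in_quote:
            return value[:i].rstrip()
        i += 1
    return value.rstrip()


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _read_quoted(value: str, context: str) -> tuple[str, str]:
    """Split ``"text" rest`` -> (unescaped text, rest)."""
    value = value.lstrip()
    if not value.startswith('"'):
        raise OboParseError(f"expected quoted string in {context}: {value!r}")
    i = 1
    while i < len(value):
        if value[i] == "\\":
            i += 2
            continue
        if value[i] == '"':
            return _unescape(value[1:i]), value[i + 1:].strip()
        i += 1
    raise OboParseError(f"unterminated quote in {context}: {value!r}")


def _read_bracket_list(rest: str, context: str) -> tuple[list[str], str]:
    """Split ``[a, b] tail`` -> (items, tail); missing brackets -> ([], rest)."""
    rest = rest.lstrip()
    if not rest.startswith("["):
        return [], rest
    end = rest.find("]")
    if end < 0:
        raise OboParseError(f"unterminated xref list in {context}: {rest!r}")
    inner = rest[1:end].strip()
    items = [x.strip() for x in inner.split(",") if x.strip()] if inner else []
    return items, rest[end + 1:].strip()


def _parse_def(value: str) -> Definition:
    text, rest = _read_quoted(value, "def")
    provs, _ = _read_bracket_list(rest, "def")
    return Definition(text=text, provenance=tuple(provs))


def _parse_synonym(value: str) -> Synonym:
    text, rest = _read_quoted(value, "synonym")
    scope = "RELATED"
    type_tag = None
    if rest and not rest.startswith("["):
        parts = rest.split(None, 2)
        scope = parts[0]
        rest = rest[len(parts[0]):].strip()
        if rest and not rest.startswith("["):
            tag = rest.split(None, 1)[0]
            type_tag = tag
            rest = rest[len(tag):].strip()
    xrefs, _ = _read_bracket_list(rest, "synonym")
    return Synonym(text=text, scope=scope, type_tag=type_tag,
                   xrefs=tuple(Identifier.parse(x) for x in xrefs))


def _parse_property_value(term: ClassTerm, value: str) -> None:
    parts = value.split(None, 1)
    if len(parts) < 2:
        raise OboParseError(f"malformed property_value: {value!r}")
    prop, rest = parts
    if prop == EXTERNAL_DEFINITION_PROP:
        text, tail = _read_quoted(rest, "property_value")
        provs, _ = _read_bracket_list(tail, "property_value")
        term.external_definitions.append(
            Definition(text=text, provenance=tuple(provs), is_external=True))
    elif prop == PROVENANCE_PROP:
        term.provenance.append(rest.strip())
    else:
        term.pass_through.append(("property_value", value))


# ---------------------------------------------------------------------------
# parse

def parse_obo(source: Union[str, TextIO]) -> Ontology:
    """Parse an OBO document (string or text stream) into an :class:`Ontology`.

    Relationship properties not present in the default registry are
    auto-registered with a warning.  Definition xrefs become
    ``Definition.provenance``; unknown tags are kept as pass-through.
    """
    text = source if isinstance(source, str) else source.read()
    header: list[tuple[str, str]] = []
    stanzas: list[tuple[str, list[tuple[str, str]]]] = []
    current: list[tuple[str, str]] | None = None
    current_type = None

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current_type = line[1:-1]
            current = []
            stanzas.append((current_type, current))
            continue
        tag, sep, value = line.partition(":")
        if not sep:
            raise OboParseError(f"malformed line: {raw!r}")
        tag = tag.strip()
        value = value.strip()
        if current is None:
            header.append((tag, value))
        else:
            current.append((tag, value))

    onto = Ontology(header=header)

    # first pass: declare classes (axioms may point forward)
    pending_axioms: list[tuple[Identifier, str, str]] = []
    for stype, tags in stanzas:
        if stype == "Typedef":
            for tag, value in tags:
                if tag == "id":
                    onto.property_registry.ensure(_strip_trailing_comment(value))
            continue
        if stype != "Term":
            continue
        ids = [v for t, v in tags if t == "id"]
        if len(ids) != 1:
            raise OboParseError(f"stanza must have exactly one id tag, got {ids}")
        term = ClassTerm(id=Identifier.parse(ids[0]))
        for tag, value in tags:
            value_nc = _strip_trailing_comment(value)
            if tag == "id":
                continue
            elif tag == "name":
                # extra labels are kept for the QC gate, not rejected here
                if term.label is None:
                    term.label = value_nc
                else:
                    term.pass_through.append(("name", value))
            elif tag == "def":
                if term.definition is None:
                    term.definition = _parse_def(value)
                else:
                    term.pass_through.append(("def", value))
            elif tag == "synonym":
                term.synonyms.append(_parse_synonym(value))
            elif tag == "xref":
                term.xrefs.append(Identifier.parse(value_nc.split()[0]))
            elif tag == "comment":
                term.comments.append(value)
            elif tag == "subset":
                term.subsets.append(value_nc)
            elif tag == "property_value":
                _parse_property_value(term, value)
            elif tag == "is_obsolete":
                term.is_obsolete = value_nc.lower() == "true"
            elif tag == "replaced_by":
                term.replaced_by.append(Identifier.parse(value_nc))
            elif tag == "consider":
                term.consider.append(Identifier.parse(value_nc))
            elif tag in ("is_a", "relationship"):
                pending_axioms.append((term.id, tag, value_nc))
            else:
                term.pass_through.append((tag, value))
        onto.add_class(term)

    for subject, tag, value in pending_axioms:
        if tag == "is_a":
            onto.add_axiom(is_a(subject, Identifier.parse(value)))
        else:
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship: {value!r}")
            prop, obj = parts[0], parts[1]
            if prop not in onto.property_registry:
                warnings.warn(f"auto-registering relationship property {prop!r}")
            onto.add_axiom(relationship(subject, prop, Identifier.parse(obj)))
    return onto


# ---------------------------------------------------------------------------
# write

def _format_def(d: Definition) -> str:
    provs = ", ".join(d.provenance)
    return f'"{_escape(d.text)}" [{provs}]'


def _format_synonym(s: Synonym) -> str:
    parts = [f'"{_escape(s.text)}"', s.scope]
    if s.type_tag:
        parts.append(s.type_tag)
    parts.append("[" + ", ".join(x.curie for x in s.xrefs) + "]")
    return " ".join(parts)


def _stanza_lines(term: ClassTerm, axioms: list[Axiom]) -> list[str]:
    lines = ["[Term]", f"id: {term.id.curie}"]
    if term.label is not None:
        lines.append(f"name: {term.label}")
    if term.definition is not None:
        lines.append(f"def: {_format_def(term.definition)}")
    for c in sorted(term.comments):
        lines.append(f"comment: {c}")
    for s in sorted(term.subsets):
        lines.append(f"subset: {s}")
    for syn in sorted(term.synonyms,
                      key=lambda s: (s.text, s.scope, s.type_tag or "")):
        lines.append(f"synonym: {_format_synonym(syn)}")
    for x in sorted(set(term.xrefs), key=lambda i: i.curie):
        lines.append(f"xref: {x.curie}")
    for d in sorted(term.external_definitions, key=lambda d: d.text):
        provs = ", ".join(d.provenance)
        bracket = f" [{provs}]" if d.provenance else ""
        lines.append(f"property_value: {EXTERNAL_DEFINITION_PROP} "
                     f'"{_escape(d.text)}"{bracket} xsd:string')
    for p in sorted(term.provenance):
        lines.append(f"property_value: {PROVENANCE_PROP} {p}")
    for tag, value in sorted(term.pass_through):
        lines.append(f"{tag}: {value}")
    if term.is_obsolete:
        # obsolete stubs never carry logical tags
        lines.append("is_obsolete: true")
        for r in sorted(term.replaced_by, key=lambda i: i.curie):
            lines.append(f"replaced_by: {r.curie}")
        for c in sorted(term.consider, key=lambda i: i.curie):
            lines.append(f"consider: {c.curie}")
        return lines
    for ax in sorted(axioms, key=Axiom.key):
        if ax.kind is AxiomKind.IS_A:
            lines.append(f"is_a: {ax.object.curie}")
        elif ax.kind is AxiomKind.RELATIONSHIP:
            lines.append(f"relationship: {ax.property} {ax.object.curie}")
        else:
            raise UnserializableAxiomError(
                f"{ax.kind.name} axiom on {ax.subject.curie} has no OBO form; "
                "equivalences belong in the mapping table")
    return lines


def write_obo(onto: Ontology) -> str:
    """Serialize an ontology to canonical OBO text (deterministic bytes)."""
    out: list[str] = []
    for k, v in onto.header:
        out.append(f"{k}: {v}")
    for ident in sorted(onto.classes, key=lambda i: i.curie):
        term = onto.classes[ident]
        out.append("")
        out.extend(_stanza_lines(term, onto.axioms_about(ident)))
    return "\n".join(out) + "\n"


def write_obo_file(onto: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_obo(onto))


def parse_obo_file(path) -> Ontology:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_obo(fh)


# ---------------------------------------------------------------------------
# mapping table

MAPPING_COLUMNS = ("source_id", "target_id", "mapping_type", "taxon",
                   "provenance")


class MappingTableError(Exception):
    pass


def read_mapping_table(source: Union[str, TextIO]):
    """Read a tab-separated mapping table into validated entries.

    Columns: source_id, target_id, mapping_type (direct|taxonomic),
    taxon (required iff taxonomic), provenance.
    """
    from .align import MappingEntry

    text = source if isinstance(source, str) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    headerrow = tuple(lines[0].rstrip("\n").split("\t"))
    if headerrow != MAPPING_COLUMNS:
        raise MappingTableError(f"bad header {headerrow!r}")
    entries = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != 5:
            raise MappingTableError(f"expected 5 columns: {ln!r}")
        src, tgt, mtype, taxon, prov = (c.strip() for c in cells)
        entries.append(MappingEntry(
            source_id=Identifier.parse(src),
            target_id=Identifier.parse(tgt),
            mapping_type=mtype,
            taxon=Identifier.parse(taxon) if taxon else None,
            provenance=prov,
        ))
    return entries


def write_mapping_table(entries) -> str:
    rows = ["\t".join(MAPPING_COLUMNS)]
    for e in entries:
        rows.append("\t".join([
            e.source_id.curie,
            e.target_id.curie,
            e.mapping_type,
            e.taxon.curie if e.taxon else "",
            e.provenance,
        ]))
    return "\n".join(rows) + "\n"


__all__ = [
    "parse_obo", "write_obo", "parse_obo_file", "write_obo_file",
    "read_mapping_table", "write_mapping_table",
    "OboParseError", "UnserializableAxiomError", "MappingTableError",
    "TAG_ORDER", "EXTERNAL_DEFINITION_PROP", "MAPPING_COLUMNS",
]
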