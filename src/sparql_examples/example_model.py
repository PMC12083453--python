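"""Data model and Turtle I/O for question–query example documents.

Each example is one Turtle file describing a single subject typed as a SHACL
``SPARQLExecutable`` (plus a form-specific subtype such as
``sh:SPARQLSelectExecutable``).  The natural-language question is an
``rdfs:comment`` with a language tag, the query text hangs off the property
matching its form (``sh:select``, ``sh:ask``, ``sh:construct``, ``sh:update``
or ``spex:describe`` — DESCRIBE has no SHACL concept, so an extension property
is used and the document is typed ``sh:SPARQLExecutable`` only), endpoints are
``schema:target`` and tags are ``schema:keywords``.  ``spex:federatesWith``
declares the remote endpoints a federated query joins with.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import urlparse

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from sparql_examples.errors import (
    CollectionError,
    ExampleParseError,
    ExampleStructureError,
    MissingQueryError,
    SerializationError,
)
from sparql_examples.namespaces import EXAMPLE_BINDINGS, SCHEMA, SCHEMA_HTTP, SH, SPEX

__all__ = [
    "PrefixMap",
    "QueryKind",
    "ExampleDocument",
    "ExampleCollection",
    "parse_example",
    "serialize_example",
    "load_collection",
    "PREFIXES_FILENAME",
]

#: Per-folder file holding shared ``sh:declare`` prefix declarations.
PREFIXES_FILENAME = "prefixes.ttl"


def canonical_example_text() -> str:
    """Turtle text of the canonical UniProt "all taxa" example."""
    from importlib import resources as importlib_resources

    return (
        importlib_resources.files("sparql_examples")
        .joinpath("resources/uniprot_taxa_example.ttl")
        .read_text(encoding="utf-8")
    )

# PN_PREFIX from the SPARQL grammar, restricted to the BMP; the empty label is
# the default prefix and is allowed.
_PN_CHARS_BASE = "A-Za-zÀ-˿Ͱ-῿Ⰰ-퟿"
_PN_CHARS = rf"0-9_\-·{_PN_CHARS_BASE}"
_PN_PREFIX_RE = re.compile(rf"^$|^[{_PN_CHARS_BASE}](?:[{_PN_CHARS}.]*[{_PN_CHARS}])?$")


def is_absolute_iri(text: str) -> bool:
    if not text or any(ch.isspace() for ch in text):
        return False
    parsed = urlparse(text)
    return bool(parsed.scheme)


class PrefixMap:
    """Ordered mapping from prefix label to absolute namespace IRI.

    Labels follow the SPARQL prefix-label grammar (the empty string denotes
    the default prefix) and are unique; namespaces must be absolute IRIs.
    """

    def __init__(self, entries: dict[str, str] | None = None):
        self._entries: dict[str, str] = {}
        for label, namespace in (entries or {}).items():
            self.add(label, namespace)

    def add(self, label: str, namespace: str) -> None:
        if not _PN_PREFIX_RE.match(label):
            raise ValueError(f"invalid prefix label: {label!r}")
        if not is_absolute_iri(namespace):
            raise ValueError(f"namespace is not an absolute IRI: {namespace!r}")
        self._entries[label] = str(namespace)

    def get(self, label: str, default: str | None = None) -> str | None:
        return self._entries.get(label, default)

    def items(self) -> list[tuple[str, str]]:
        return list(self._entries.items())

    def curie(self, iri: str) -> str | None:
        """Compact ``iri`` against the longest matching namespace, if any."""
        best: tuple[str, str] | None = None
        for label, ns in self._entries.items():
            if iri.startswith(ns) and len(iri) > len(ns):
                if best is None or len(ns) > len(best[1]):
                    best = (label, ns)
        if best is None:
            return None
        local = iri[len(best[1]) :]
        if not local or "/" in local or "#" in local:
            return None
        return f"{best[0]}:{local}"

    def merged(self, other: "PrefixMap") -> "PrefixMap":
        """New map with ``other``'s entries shadowing this one's."""
        out = PrefixMap(dict(self._entries))
        for label, ns in other.items():
            out.add(label, ns)
        return out

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PrefixMap) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"PrefixMap({self._entries!r})"


class QueryKind(enum.Enum):
    """The SPARQL form of an example query."""

    SELECT = "select"
    ASK = "ask"
    CONSTRUCT = "construct"
    UPDATE = "update"
    DESCRIBE = "describe"

    @property
    def query_property(self) -> URIRef:
        return _KIND_TO_PROPERTY[self]

    @property
    def shacl_subtype(self) -> URIRef | None:
        """Form-specific SHACL class; DESCRIBE has none (plain executable)."""
        return _KIND_TO_SUBTYPE[self]

    @classmethod
    def from_property(cls, prop: URIRef) -> "QueryKind":
        return _PROPERTY_TO_KIND[prop]


_KIND_TO_PROPERTY: dict[QueryKind, URIRef] = {
    QueryKind.SELECT: SH.select,
    QueryKind.ASK: SH.ask,
    QueryKind.CONSTRUCT: SH.construct,
    QueryKind.UPDATE: SH.update,
    QueryKind.DESCRIBE: SPEX.describe,
}
_PROPERTY_TO_KIND = {v: k for k, v in _KIND_TO_PROPERTY.items()}
_KIND_TO_SUBTYPE: dict[QueryKind, URIRef | None] = {
    QueryKind.SELECT: SH.SPARQLSelectExecutable,
    QueryKind.ASK: SH.SPARQLAskExecutable,
    QueryKind.CONSTRUCT: SH.SPARQLConstructExecutable,
    QueryKind.UPDATE: SH.SPARQLUpdateExecutable,
    QueryKind.DESCRIBE: None,
}
_SUBTYPE_TO_KIND = {v: k for k, v in _KIND_TO_SUBTYPE.items() if v is not None}


@dataclass
class ExampleDocument:
    """One question–query pair with its metadata.

    ``comments`` are ``(text, language-tag-or-None)`` pairs; ``declared_types``
    retains the rdf:types found in the source file so that validation can
    check them against ``kind`` later.  A parsed document may violate
    invariants (e.g. a blank-node subject gives ``identifier=None``); use
    :meth:`invariant_violations` or the validation module to find out.
    """

    identifier: str | None
    kind: QueryKind
    query_text: str
    comments: list[tuple[str, str | None]] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    federates_with: list[str] = field(default_factory=list)
    prefixes: PrefixMap = field(default_factory=PrefixMap)
    #: rdf:types found in the source file; None means "constructed in memory",
    #: which defaults to the correct types for ``kind``.  An empty list means
    #: the source file really declared no type.
    declared_types: list[str] | None = None

    def __post_init__(self) -> None:
        if self.declared_types is None:
            types = [str(SH.SPARQLExecutable)]
            if self.kind.shacl_subtype is not None:
                types.insert(0, str(self.kind.shacl_subtype))
            self.declared_types = types

    def invariant_violations(self) -> list[str]:
        problems = []
        if self.identifier is None or not is_absolute_iri(self.identifier):
            problems.append("identifier must be an absolute IRI")
        if not self.query_text.strip():
            problems.append("query_text must be non-empty")
        if not self.comments:
            problems.append("comments must be non-empty")
        elif not any(lang for _, lang in self.comments):
            problems.append("at least one comment must carry a language tag")
        if not self.targets:
            problems.append("targets must be non-empty")
        return problems

    def question(self, language: str = "en") -> str | None:
        """First comment in ``language``, falling back to the first comment."""
        for text, lang in self.comments:
            if lang == language:
                return text
        return self.comments[0][0] if self.comments else None

    @property
    def declares_federation(self) -> bool:
        return bool(self.federates_with) or "federated" in self.keywords

    def to_graph(self) -> Graph:
        """RDF form of the document (the graph :func:`serialize_example` writes)."""
        g = Graph()
        for label, ns in EXAMPLE_BINDINGS.items():
            g.bind(label, ns)
        subject: URIRef | BNode
        subject = URIRef(self.identifier) if self.identifier else BNode()
        subtype = self.kind.shacl_subtype
        if subtype is not None:
            g.add((subject, RDF.type, subtype))
        g.add((subject, RDF.type, SH.SPARQLExecutable))
        for text, lang in self.comments:
            g.add((subject, RDFS.comment, Literal(text, lang=lang)))
        g.add((subject, self.kind.query_property, Literal(self.query_text)))
        for target in self.targets:
            g.add((subject, SCHEMA.target, URIRef(target)))
        for keyword in self.keywords:
            g.add((subject, SCHEMA.keywords, Literal(keyword)))
        for endpoint in self.federates_with:
            g.add((subject, SPEX.federatesWith, URIRef(endpoint)))
        if len(self.prefixes):
            node = BNode()
            g.add((subject, SH.prefixes, node))
            for label, ns in self.prefixes.items():
                decl = BNode()
                g.add((node, SH.declare, decl))
                g.add((decl, SH.prefix, Literal(label)))
                g.add((decl, SH.namespace, Literal(ns, datatype=XSD.anyURI)))
        return g


@dataclass
class ExampleCollection:
    """All examples of a repository, grouped by contributing resource folder."""

    examples: list[ExampleDocument] = field(default_factory=list)
    resource_of: dict[str, str] = field(default_factory=dict)
    source_of: dict[str, str] = field(default_factory=dict)
    load_failures: list[tuple[str, str]] = field(default_factory=list)
    duplicates: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.examples)

    def by_resource(self) -> dict[str, list[ExampleDocument]]:
        grouped: dict[str, list[ExampleDocument]] = {}
        for example in self.examples:
            key = self.resource_of.get(example.identifier or "", "")
            grouped.setdefault(key, []).append(example)
        return grouped


# ---------------------------------------------------------------------------
# parsing


def _parse_turtle(turtle_text: str, base_iri: str) -> Graph:
    g = Graph()
    try:
        g.parse(data=turtle_text, format="turtle", publicID=base_iri)
    except Exception as exc:  # rdflib's notation3 raises BadSyntax
        raise ExampleParseError(f"malformed Turtle: {exc}") from exc
    return g


def _extract_prefix_declarations(g: Graph, node) -> PrefixMap:
    pm = PrefixMap()
    declarations = []
    for decl in g.objects(node, SH.declare):
        labels = list(g.objects(decl, SH.prefix))
        namespaces = list(g.objects(decl, SH.namespace))
        if labels and namespaces:
            declarations.append((str(labels[0]), str(namespaces[0])))
    for label, ns in sorted(declarations):
        try:
            pm.add(label, ns)
        except ValueError:
            continue  # a broken declaration is reported by validation, not here
    return pm


def _schema_objects(g: Graph, subject, local: str):
    yield from g.objects(subject, SCHEMA[local])
    yield from g.objects(subject, SCHEMA_HTTP[local])


def example_from_graph(g: Graph) -> ExampleDocument:
    """Build an :class:`ExampleDocument` from a graph holding exactly one example."""
    found: list[tuple[object, URIRef]] = []
    for prop in _PROPERTY_TO_KIND:
        for subject in g.subjects(prop, None):
            found.append((subject, prop))
    if not found:
        if any(g.subjects(RDF.type, SH.SPARQLExecutable)):
            raise MissingQueryError("example subject has no query property")
        raise ExampleStructureError("document contains no example subject")
    subjects = {s for s, _ in found}
    if len(subjects) > 1:
        raise ExampleStructureError(
            f"document contains {len(subjects)} example subjects; expected exactly one"
        )
    if len(found) > 1:
        raise ExampleStructureError(
            "example subject carries multiple query properties; one query per file"
        )
    subject, prop = found[0]
    kind = QueryKind.from_property(prop)

    query_values = list(g.objects(subject, prop))
    query_text = str(query_values[0])

    comments = sorted(
        (str(o), o.language if isinstance(o, Literal) else None)
        for o in g.objects(subject, RDFS.comment)
    )
    targets = sorted(str(o) for o in _schema_objects(g, subject, "target"))
    keywords = sorted(str(o) for o in _schema_objects(g, subject, "keywords"))
    federates = sorted(str(o) for o in g.objects(subject, SPEX.federatesWith))
    declared_types = sorted(str(o) for o in g.objects(subject, RDF.type))

    prefixes = PrefixMap()
    for node in g.objects(subject, SH.prefixes):
        prefixes = prefixes.merged(_extract_prefix_declarations(g, node))

    return ExampleDocument(
        identifier=str(subject) if isinstance(subject, URIRef) else None,
        kind=kind,
        query_text=query_text,
        comments=comments,
        targets=targets,
        keywords=keywords,
        federates_with=federates,
        prefixes=prefixes,
        declared_types=declared_types,
    )


def parse_example(turtle_text: str, base_iri: str = "https://example.org/") -> ExampleDocument:
    """Parse one Turtle example document.

    Raises :class:`ExampleParseError` for malformed Turtle,
    :class:`ExampleStructureError` when the document does not describe exactly
    one example subject, and :class:`MissingQueryError` when the subject has
    no query property.
    """
    return example_from_graph(_parse_turtle(turtle_text, base_iri))


def serialize_example(example: ExampleDocument) -> str:
    """Serialize to Turtle; refuses documents violating an invariant.

    ``parse_example(serialize_example(x))`` is RDF-graph-isomorphic to
    ``x.to_graph()``.
    """
    problems = example.invariant_violations()
    if problems:
        raise SerializationError(f"refusing to serialize: {problems[0]}")
    return example.to_graph().serialize(format="turtle")


# ---------------------------------------------------------------------------
# collection loading


def load_collection(root_folder: str | Path, strict_duplicates: bool = True) -> ExampleCollection:
    """Load every ``.ttl`` example under ``root_folder``'s resource subfolders.

    Each example's resource is the name of the folder that holds its file.  A
    ``prefixes.ttl`` file in a folder supplies shared ``sh:declare`` prefix
    declarations to examples that reference a prefixes node not defined in
    their own file.  Unreadable files are recorded as load failures, not
    raised.  Duplicate identifiers raise :class:`CollectionError` (or are
    recorded when ``strict_duplicates`` is false, so that validation can
    report them).
    """
    root = Path(root_folder)
    if not root.is_dir():
        raise CollectionError(f"not a folder: {root}")

    collection = ExampleCollection()
    seen: dict[str, str] = {}
    ttl_files = sorted(p for p in root.rglob("*.ttl") if p.is_file())

    folder_prefixes: dict[Path, PrefixMap] = {}
    for path in ttl_files:
        if path.name != PREFIXES_FILENAME:
            continue
        try:
            g = _parse_turtle(path.read_text(encoding="utf-8"), path.resolve().as_uri())
        except ExampleParseError as exc:
            collection.load_failures.append((str(path), str(exc)))
            continue
        pm = PrefixMap()
        for node in set(g.subjects(SH.declare, None)):
            pm = pm.merged(_extract_prefix_declarations(g, node))
        folder_prefixes[path.parent] = pm

    for path in ttl_files:
        if path.name == PREFIXES_FILENAME:
            continue
        try:
            example = parse_example(path.read_text(encoding="utf-8"), base_iri=path.resolve().as_uri())
        except Exception as exc:
            collection.load_failures.append((str(path), str(exc)))
            continue
        if not len(example.prefixes) and path.parent in folder_prefixes:
            example.prefixes = folder_prefixes[path.parent]
        identifier = example.identifier
        if identifier is not None:
            if identifier in seen:
                if strict_duplicates:
                    raise CollectionError(
                        f"duplicate identifier {identifier} in {seen[identifier]} and {path}"
                    )
                collection.duplicates.append((identifier, seen[identifier], str(path)))
            else:
                seen[identifier] = str(path)
                collection.source_of[identifier] = str(path)
        resource = path.parent.name if path.parent != root else ""
        collection.examples.append(example)
        if identifier is not None and identifier not in collection.resource_of:
            collection.resource_of[identifier] = resource
    return collection
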