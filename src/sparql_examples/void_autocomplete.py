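"""VoID dataset descriptions, autocomplete suggestions, compliance checking.

A VoID description summarizes what an RDF dataset contains: how many triples,
which classes (with entity counts), which predicates (with triple counts),
and — as an extension — which properties connect which subject classes to
which object classes or datatypes.  That linkage is exactly what a query
editor needs to offer *precise* autocomplete: when the focused variable's
class is known, only properties actually stated for that class are suggested,
ranked by how often they occur.

The same machinery powers an endpoint-metadata compliance checker: a
well-prepared endpoint publishes both its example queries (in the
``.well-known/sparql-examples`` named graph) and a VoID description; the
checker verifies both and suggests concrete remediation steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import BNode, Dataset, Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from sparql_examples.errors import SparqlExamplesError
from sparql_examples.example_model import example_from_graph
from sparql_examples.fixer import DEFAULT_COMMON_PREFIXES
from sparql_examples.example_model import PrefixMap
from sparql_examples.namespaces import VOID, VOID_EXT
from sparql_examples.publishing import named_graph_iri
from sparql_examples.validation import validate_example

__all__ = [
    "UNKNOWN_CLASS",
    "VoidDescription",
    "Suggestion",
    "ComplianceReport",
    "generate_void",
    "suggest_completions",
    "check_metadata_compliance",
    "void_from_graph",
]

#: Marker used when a subject or object has no rdf:type (and is not a literal).
UNKNOWN_CLASS = "urn:sparql-examples:unknown-class"


@dataclass
class VoidDescription:
    """Dataset statistics: classes, predicates, cardinalities and linkage."""

    dataset_iri: str
    total_triples: int
    class_partitions: list[tuple[str, int]] = field(default_factory=list)
    property_partitions: list[tuple[str, int]] = field(default_factory=list)
    linkage: list[tuple[str, str, str, int]] = field(default_factory=list)

    def class_count(self, class_iri: str) -> int:
        return dict(self.class_partitions).get(class_iri, 0)

    def property_count(self, property_iri: str) -> int:
        return dict(self.property_partitions).get(property_iri, 0)

    def properties_of_class(self, class_iri: str) -> dict[str, int]:
        """Property → triple count over subjects typed with ``class_iri``."""
        out: dict[str, int] = {}
        for subject_class, prop, _object_class, count in self.linkage:
            if subject_class == class_iri:
                out[prop] = out.get(prop, 0) + count
        return out

    def to_graph(self) -> Graph:
        """Serialize as a VoID document (standard terms + linkage extension)."""
        g = Graph()
        g.bind("void", VOID)
        g.bind("void-ext", VOID_EXT)
        ds = URIRef(self.dataset_iri)
        g.add((ds, RDF.type, VOID.Dataset))
        g.add((ds, VOID.triples, Literal(self.total_triples)))
        class_nodes: dict[str, BNode] = {}
        for class_iri, entities in self.class_partitions:
            node = BNode()
            class_nodes[class_iri] = node
            g.add((ds, VOID.classPartition, node))
            g.add((node, VOID["class"], URIRef(class_iri)))
            g.add((node, VOID.entities, Literal(entities)))
        for property_iri, triples in self.property_partitions:
            node = BNode()
            g.add((ds, VOID.propertyPartition, node))
            g.add((node, VOID.property, URIRef(property_iri)))
            g.add((node, VOID.triples, Literal(triples)))
        for subject_class, prop, object_class, count in self.linkage:
            parent = class_nodes.get(subject_class)
            node = BNode()
            if parent is not None:
                g.add((parent, VOID.propertyPartition, node))
            else:
                g.add((ds, VOID.propertyPartition, node))
                g.add((node, VOID_EXT.subjectClass, URIRef(subject_class)))
            g.add((node, VOID.property, URIRef(prop)))
            g.add((node, VOID.triples, Literal(count)))
            g.add((node, VOID_EXT.objectClassPartition, URIRef(object_class)))
        return g

    def serialize(self) -> str:
        return self.to_graph().serialize(format="turtle")


def generate_void(dataset: Graph, dataset_iri: str) -> VoidDescription:
    """Compute a VoID description by exhaustive counting over ``dataset``.

    Class partitions count distinct typed subjects; property partitions count
    triples per predicate (their counts sum to the total triple count).
    Linkage rows count (subject class, property, object class-or-datatype)
    co-occurrences; untyped subjects/objects use an unknown-class marker, and
    a subject with several types contributes one row per type.
    """
    types: dict[object, list[str]] = {}
    for s, o in dataset.subject_objects(RDF.type):
        types.setdefault(s, []).append(str(o))
    for type_list in types.values():
        type_list.sort()

    class_entities: dict[str, set] = {}
    property_counts: dict[str, int] = {}
    linkage_counts: dict[tuple[str, str, str], int] = {}

    for s, p, o in dataset:
        prop = str(p)
        property_counts[prop] = property_counts.get(prop, 0) + 1
        if p == RDF.type and isinstance(o, URIRef):
            class_entities.setdefault(str(o), set()).add(s)
        if isinstance(o, Literal):
            object_class = str(o.datatype) if o.datatype else (
                str(RDF.langString) if o.language else str(XSD.string)
            )
        else:
            object_types = types.get(o)
            object_class = object_types[0] if object_types else UNKNOWN_CLASS
        for subject_class in types.get(s, [UNKNOWN_CLASS]):
            key = (subject_class, prop, object_class)
            linkage_counts[key] = linkage_counts.get(key, 0) + 1

    return VoidDescription(
        dataset_iri=dataset_iri,
        total_triples=len(dataset),
        class_partitions=sorted((c, len(s)) for c, s in class_entities.items()),
        property_partitions=sorted(property_counts.items()),
        linkage=sorted((s, p, o, n) for (s, p, o), n in linkage_counts.items()),
    )


def void_from_graph(graph: Graph) -> VoidDescription | None:
    """Read back a VoID description from RDF, if one is present."""
    datasets = list(graph.subjects(RDF.type, VOID.Dataset))
    if not datasets:
        return None
    ds = sorted(datasets)[0]
    totals = list(graph.objects(ds, VOID.triples))
    class_partitions = []
    for node in graph.objects(ds, VOID.classPartition):
        classes = list(graph.objects(node, VOID["class"]))
        entities = list(graph.objects(node, VOID.entities))
        if classes:
            class_partitions.append((str(classes[0]), int(entities[0]) if entities else 0))
    property_partitions = []
    for node in graph.objects(ds, VOID.propertyPartition):
        props = list(graph.objects(node, VOID.property))
        triples = list(graph.objects(node, VOID.triples))
        if props:
            property_partitions.append((str(props[0]), int(triples[0]) if triples else 0))
    return VoidDescription(
        dataset_iri=str(ds),
        total_triples=int(totals[0]) if totals else 0,
        class_partitions=sorted(class_partitions),
        property_partitions=sorted(property_partitions),
    )


# ---------------------------------------------------------------------------
# autocomplete


@dataclass
class Suggestion:
    iri: str
    curie: str
    count: int
    scoped: bool = True  # False: focus class unknown, fell back to all properties


def _curie_for(iri: str, prefixes: PrefixMap) -> str:
    return prefixes.curie(iri) or iri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]


def _matches(partial: str, iri: str, curie: str) -> bool:
    if not partial:
        return True
    needle = partial.lower()
    local = iri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1].lower()
    return curie.lower().startswith(needle) or local.startswith(needle)


def suggest_completions(
    void: VoidDescription,
    position: str,
    focus_class: str | None = None,
    partial: str = "",
    prefixes: PrefixMap | None = None,
) -> list[Suggestion]:
    """Rank completion candidates from a VoID description.

    ``position`` is ``"predicate"`` or ``"class"``.  With a known focus class,
    predicate suggestions are restricted to properties the linkage actually
    states for that class; an unknown class falls back to all property
    partitions, flagged unscoped.  Candidates are filtered by case-insensitive
    prefix match of ``partial`` against the CURIE or local name, then ranked
    by descending occurrence count and lexicographic IRI.
    """
    if position not in ("predicate", "class"):
        raise ValueError(f"position must be 'predicate' or 'class', got {position!r}")
    prefixes = prefixes or PrefixMap(DEFAULT_COMMON_PREFIXES)

    scoped = True
    if position == "class":
        candidates = dict(void.class_partitions)
    elif focus_class is not None and any(c == focus_class for c, _ in void.class_partitions):
        candidates = void.properties_of_class(focus_class)
    else:
        candidates = dict(void.property_partitions)
        scoped = focus_class is None  # explicit-but-unknown class: flag the fallback

    suggestions = [
        Suggestion(iri, _curie_for(iri, prefixes), count, scoped)
        for iri, count in candidates.items()
        if _matches(partial, iri, _curie_for(iri, prefixes))
    ]
    suggestions.sort(key=lambda s: (-s.count, s.iri))
    return suggestions


# ---------------------------------------------------------------------------
# endpoint metadata compliance


@dataclass
class ComplianceReport:
    has_examples_graph: bool
    has_void: bool
    example_count: int
    suggestions: list[str] = field(default_factory=list)

    @property
    def compliant(self) -> bool:
        return not self.suggestions


def check_metadata_compliance(dataset: Dataset | str, endpoint: str) -> ComplianceReport:
    """Check a dataset dump for the two published-metadata requirements.

    C1: the ``.well-known/sparql-examples`` named graph for ``endpoint``
    exists and holds at least one *well-formed* example (validated with the
    standard metadata rules; invalid examples are not counted).  C2: a VoID
    description with at least one class partition is present in some graph.
    Each failed check yields a concrete remediation suggestion.
    """
    if isinstance(dataset, str):
        ds = Dataset()
        try:
            ds.parse(dataset)
        except Exception as exc:
            raise SparqlExamplesError(f"unreadable dataset dump: {exc}") from exc
    else:
        ds = dataset

    graph_iri = named_graph_iri(endpoint)
    suggestions: list[str] = []

    examples_graph = None
    for graph in ds.graphs():
        if str(graph.identifier) == graph_iri and len(graph) > 0:
            examples_graph = graph
            break

    example_count = 0
    if examples_graph is not None:
        example_count, invalid_count = _count_valid_examples(examples_graph)
        has_examples_graph = True
        if example_count == 0:
            suggestions.append(
                f"graph <{graph_iri}> contains no well-formed example; validate the "
                "collection and re-publish the merged examples file"
            )
        elif invalid_count:
            suggestions.append(
                f"graph <{graph_iri}> contains {invalid_count} malformed example(s); "
                "run validation on the collection and fix the reported issues"
            )
    else:
        has_examples_graph = False
        suggestions.append(
            f"publish the merged example queries to the named graph <{graph_iri}> "
            "(merge the collection for this endpoint and upload the Turtle file)"
        )

    void_description = None
    for graph in ds.graphs():
        void_description = void_from_graph(graph)
        if void_description is not None:
            break
    if void_description is None:
        default = getattr(ds, "default_graph", None)
        void_description = void_from_graph(ds if default is None else default)
    has_void = void_description is not None and bool(void_description.class_partitions)
    if not has_void:
        suggestions.append(
            "no VoID description with class partitions found; generate one from the "
            "dataset (generate_void) and publish it alongside the data"
        )

    return ComplianceReport(
        has_examples_graph=has_examples_graph,
        has_void=has_void,
        example_count=example_count,
        suggestions=suggestions,
    )


def _count_valid_examples(graph: Graph) -> tuple[int, int]:
    """(well-formed, malformed) example counts in a published graph."""
    from sparql_examples.namespaces import SH, SPEX

    query_properties = [SH.select, SH.ask, SH.construct, SH.update, SPEX.describe]
    subjects = set()
    for prop in query_properties:
        subjects.update(graph.subjects(prop, None))
    valid = invalid = 0
    for subject in subjects:
        scoped = Graph()
        _copy_subject(graph, subject, scoped, set())
        try:
            example = example_from_graph(scoped)
        except Exception:
            invalid += 1
            continue
        if validate_example(example).passed:
            valid += 1
        else:
            invalid += 1
    return valid, invalid


def _copy_subject(source: Graph, node, target: Graph, seen: set) -> None:
    if node in seen:
        return
    seen.add(node)
    for p, o in source.predicate_objects(node):
        target.add((node, p, o))
        if isinstance(o, BNode):
            _copy_subject(source, o, target, seen)
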