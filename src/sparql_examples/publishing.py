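"""Publish examples: merged per-endpoint graphs, query search, JSON export.

Examples targeting an endpoint are merged into one graph meant to be uploaded
to the endpoint itself, under a named graph whose IRI is the endpoint address
joined with the ``.well-known/sparql-examples`` suffix.  Once published,
examples can be found with plain SPARQL ("querying for queries"), e.g. by a
substring match on the question text.  The collection can also be exported as
the JSON consumed by the Bio-Query template-search interface, with categories
named after the contributing resource folders.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

from rdflib import Graph, Literal

from sparql_examples.errors import SparqlExamplesError
from sparql_examples.example_model import ExampleCollection, ExampleDocument, is_absolute_iri
from sparql_examples.namespaces import EXAMPLE_BINDINGS

__all__ = [
    "MergedGraph",
    "named_graph_iri",
    "merge_collection",
    "query_for_queries",
    "export_bioquery_json",
    "QUERY_SEARCH_TEMPLATE",
]

WELL_KNOWN_SUFFIX = ".well-known/sparql-examples"

#: The "querying for queries" SELECT pattern: every published SELECT example
#: with its question, filtered by a substring of the question text.
QUERY_SEARCH_TEMPLATE = """\
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX sh: <http://www.w3.org/ns/shacl#>
SELECT * WHERE {{
    ?ex sh:select ?query .
    ?ex rdfs:comment ?question .
    FILTER (contains({question_expr}, {keyword_expr}))
}}"""


def named_graph_iri(endpoint: str) -> str:
    """Named-graph IRI for an endpoint's published examples.

    The suffix ``.well-known/sparql-examples`` is appended directly when the
    endpoint IRI ends with a slash, otherwise after an added slash.
    """
    if not is_absolute_iri(endpoint):
        raise SparqlExamplesError(f"endpoint must be an absolute IRI: {endpoint!r}")
    if endpoint.endswith("/"):
        return endpoint + WELL_KNOWN_SUFFIX
    return endpoint + "/" + WELL_KNOWN_SUFFIX


@dataclass
class MergedGraph:
    """All examples targeting one endpoint, as a single publishable graph."""

    endpoint: str
    graph_iri: str
    triples: Graph
    example_count: int

    def serialize(self) -> str:
        return self.triples.serialize(format="turtle")


def merge_collection(collection: ExampleCollection, endpoint: str) -> MergedGraph:
    """Merge every example whose targets include ``endpoint`` into one graph.

    Shared prefix declarations are materialized per example so the merged
    document is self-contained.  Warns when nothing matches.
    """
    graph_iri = named_graph_iri(endpoint)
    merged = Graph(identifier=graph_iri)
    for label, ns in EXAMPLE_BINDINGS.items():
        merged.bind(label, ns)
    count = 0
    for example in collection.examples:
        if endpoint in example.targets:
            merged += example.to_graph()
            count += 1
    if count == 0:
        warnings.warn(f"no examples target {endpoint}; merged graph is empty", stacklevel=2)
    return MergedGraph(endpoint=endpoint, graph_iri=graph_iri, triples=merged, example_count=count)


def _sparql_string_literal(text: str) -> str:
    escaped = text.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def query_for_queries(
    merged: MergedGraph | Graph, keyword: str, case_sensitive: bool = True
) -> list[tuple[str, str, str]]:
    """Find published SELECT examples whose question contains ``keyword``.

    Runs the standard "querying for queries" pattern over the merged graph.
    Matching is a plain case-sensitive ``contains`` on the question literal
    (pass ``case_sensitive=False`` to fold case).  Returns
    ``(example IRI, question text, query text)`` rows sorted by example IRI.
    """
    graph = merged.triples if isinstance(merged, MergedGraph) else merged
    if case_sensitive:
        question_expr, keyword_expr = "?question", _sparql_string_literal(keyword)
    else:
        question_expr = "lcase(str(?question))"
        keyword_expr = f"lcase({_sparql_string_literal(keyword)})"
    query = QUERY_SEARCH_TEMPLATE.format(question_expr=question_expr, keyword_expr=keyword_expr)
    rows = sorted(
        (str(row.ex), str(row.question), str(row.query))
        for row in graph.query(query)
    )
    # one row per example: a multilingual example matches once, with its
    # lexicographically first matching question
    seen: set[str] = set()
    unique = []
    for example_iri, question, query_text in rows:
        if example_iri not in seen:
            seen.add(example_iri)
            unique.append((example_iri, question, query_text))
    return unique


def export_bioquery_json(collection: ExampleCollection) -> str:
    """JSON records for the Bio-Query template-search interface.

    One record per example, ordered by identifier: the category is the
    contributing resource folder, the label is the first English question
    (falling back to the first question in any language).
    """
    records = []
    for example in sorted(collection.examples, key=lambda e: e.identifier or ""):
        identifier = example.identifier or ""
        records.append(
            {
                "id": identifier,
                "category": collection.resource_of.get(identifier, ""),
                "label": _bioquery_label(example),
                "query": example.query_text,
                "endpoints": list(example.targets),
                "keywords": list(example.keywords),
            }
        )
    return json.dumps(records, indent=2, ensure_ascii=False)


def _bioquery_label(example: ExampleDocument) -> str:
    for text, lang in example.comments:
        if lang == "en":
            return text
    return example.comments[0][0] if example.comments else ""
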