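"""Per-query and per-collection complexity metrics.

The central quantity is the triple-pattern (TP) count, a proxy for the number
of join hops a query needs.  Counting convention: basic triple patterns are
counted in *all* group graph patterns — OPTIONAL, UNION branches, MINUS,
subqueries, SERVICE bodies and (NOT) EXISTS filters.  A sequence property
path of length *k* counts as *k* patterns (it decomposes into *k* joins);
non-decomposable path operators (alternation, ``*``/``+``/``?``, negated
sets) and inverse wrappers do not multiply the count.  VALUES clauses
contribute nothing, as they do not traverse the graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

from sparql_examples import _sparql
from sparql_examples.errors import AnalysisError, QuerySyntaxError
from sparql_examples.example_model import ExampleCollection, ExampleDocument, PrefixMap
from sparql_examples.fixer import PrefixRegistry, add_missing_prefixes

__all__ = ["QueryMetrics", "EndpointStats", "CollectionStats", "analyze_query", "collection_stats"]

AGGREGATE_FUNCTIONS = ("SUM", "COUNT", "AVG", "MIN", "MAX", "GROUP_CONCAT", "SAMPLE")

_AGGREGATE_NODE_NAMES = {
    "Aggregate_Count": "COUNT",
    "Aggregate_Sum": "SUM",
    "Aggregate_Avg": "AVG",
    "Aggregate_Min": "MIN",
    "Aggregate_Max": "MAX",
    "Aggregate_GroupConcat": "GROUP_CONCAT",
    "Aggregate_Sample": "SAMPLE",
}


@dataclass
class QueryMetrics:
    """Complexity summary of one query."""

    triple_pattern_count: int
    aggregate_counts: dict[str, int] = field(default_factory=dict)
    service_endpoints: list[str] = field(default_factory=list)
    uses_optional: bool = False
    uses_union: bool = False
    uses_subquery: bool = False
    uses_property_path: bool = False
    uses_filter: bool = False
    projected_variables: list[str] = field(default_factory=list)

    @property
    def is_federated(self) -> bool:
        return bool(self.service_endpoints)

    @property
    def total_aggregations(self) -> int:
        return sum(self.aggregate_counts.values())


def analyze_query(query_text: str, prefixes: PrefixMap | None = None) -> QueryMetrics:
    """Compute :class:`QueryMetrics` for one query.

    ``prefixes`` supplies declarations for labels the query text itself does
    not declare.  Unparseable queries raise :class:`AnalysisError`.
    """
    text = query_text
    if prefixes is not None and len(prefixes):
        try:
            text = add_missing_prefixes(query_text, PrefixRegistry.from_map(prefixes)).fixed_query
        except Exception:
            pass
    # Aggregates are counted on a fresh parse tree: algebra translation both
    # mutates the tree (HAVING clauses are consumed) and inserts implicit
    # SAMPLE nodes for non-grouped projections, which are not aggregate
    # applications written in the query.
    from rdflib.plugins.sparql.parser import parseQuery

    try:
        parsed = _sparql.strict_parse(text)
        fresh_tree = parseQuery(text)
    except QuerySyntaxError as exc:
        raise AnalysisError(str(exc)) from exc

    triples = _sparql.collect_triples(parsed.algebra)
    tp_count = sum(_sparql.decomposed_path_length(t[1]) for t in triples)

    aggregate_counts: dict[str, int] = {}
    for node in _sparql.walk_nodes(fresh_tree):
        fn = _AGGREGATE_NODE_NAMES.get(node.name)
        if fn is not None:
            aggregate_counts[fn] = aggregate_counts.get(fn, 0) + 1

    algebra_names = {node.name for node in _sparql.walk_nodes(parsed.algebra)}
    project_count = sum(
        1 for node in _sparql.walk_nodes(parsed.algebra) if node.name == "Project"
    )

    projected: list[str] = []
    if parsed.form == "select":
        projected = [str(v) for v in parsed.algebra.get("PV", [])]

    return QueryMetrics(
        triple_pattern_count=tp_count,
        aggregate_counts=aggregate_counts,
        service_endpoints=_sparql.service_endpoints(parsed.algebra),
        uses_optional="LeftJoin" in algebra_names or "OptionalGraphPattern" in algebra_names,
        uses_union="Union" in algebra_names,
        uses_subquery=project_count > (1 if parsed.form == "select" else 0),
        uses_property_path=any(_sparql.is_path(t[1]) for t in triples),
        uses_filter="Filter" in algebra_names,
        projected_variables=projected,
    )


@dataclass
class EndpointStats:
    """One row of the per-endpoint statistics table."""

    endpoint: str
    query_count: int = 0
    federated_count: int = 0
    tp_total: int = 0
    total_aggregations: int = 0

    @property
    def mean_triple_patterns(self) -> Fraction:
        """Exact mean; round only for display."""
        if self.query_count == 0:
            return Fraction(0)
        return Fraction(self.tp_total, self.query_count)


@dataclass
class CollectionStats:
    """Per-endpoint complexity statistics over a whole collection.

    An example with several targets contributes to every target's row.
    Unanalyzable examples are excluded and listed in ``skipped``.
    """

    rows: list[EndpointStats] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def row(self, endpoint: str) -> EndpointStats | None:
        for r in self.rows:
            if r.endpoint == endpoint:
                return r
        return None

    def to_tsv(self) -> str:
        lines = ["endpoint\tqueries\tfederated\tmean_triple_patterns\ttotal_aggregations"]
        for r in self.rows:
            mean = float(r.mean_triple_patterns)
            lines.append(
                f"{r.endpoint}\t{r.query_count}\t{r.federated_count}\t{mean:.1f}\t{r.total_aggregations}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "endpoint": r.endpoint,
                    "queries": r.query_count,
                    "federated": r.federated_count,
                    "mean_triple_patterns": round(float(r.mean_triple_patterns), 1),
                    "total_aggregations": r.total_aggregations,
                }
                for r in self.rows
            ],
            indent=2,
        )


def collection_stats(collection: ExampleCollection) -> CollectionStats:
    """Aggregate :func:`analyze_query` over a collection, one row per endpoint."""
    stats = CollectionStats()
    by_endpoint: dict[str, EndpointStats] = {}
    for example in collection.examples:
        try:
            metrics = analyze_example(example)
        except AnalysisError as exc:
            stats.skipped.append((example.identifier or "<no id>", str(exc)))
            continue
        for endpoint in example.targets:
            row = by_endpoint.setdefault(endpoint, EndpointStats(endpoint))
            row.query_count += 1
            row.tp_total += metrics.triple_pattern_count
            row.total_aggregations += metrics.total_aggregations
            if metrics.is_federated:
                row.federated_count += 1
    stats.rows = [by_endpoint[e] for e in sorted(by_endpoint)]
    return stats


def analyze_example(example: ExampleDocument) -> QueryMetrics:
    """Metrics for one example document, using its attached prefix map."""
    return analyze_query(example.query_text, example.prefixes)
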