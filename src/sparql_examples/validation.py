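"""Syntax, metadata and consistency checks for example documents.

Six rules are applied per example:

R1
    The query text parses under the strict SPARQL 1.1 grammar after prefix
    expansion.  Two independent stages are run — grammar parse and algebra
    translation — emulating a dual-parser check with a single parser library.
R2
    Mandatory fields are present: identifier, declared type, at least one
    comment and at least one target endpoint.
R3
    At least one comment carries a BCP-47 language tag.
R4
    The declared SHACL subtype agrees with the query property used *and* with
    the form of the parsed query (a ``sh:select`` holding an ASK is an error).
R5
    An example declared federated (``spex:federatesWith`` or the keyword
    ``federated``) must actually contain a SERVICE clause — detected on the
    parsed algebra, not by substring search, so the word "service" in a
    literal never triggers it.
R6
    A SERVICE clause without a federation declaration is flagged as a warning.

All findings are *reported*, never raised.  The same rules are also shipped
as a SHACL shapes document (``resources/example_shapes.ttl``) for use with
external SHACL engines; this module evaluates them natively.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from urllib.request import Request, urlopen

from rdflib import Graph

from sparql_examples import _sparql
from sparql_examples.errors import QuerySyntaxError, UpdateQueryRefused
from sparql_examples.example_model import (
    ExampleCollection,
    ExampleDocument,
    QueryKind,
    is_absolute_iri,
)
from sparql_examples.fixer import PrefixRegistry, add_missing_prefixes
from sparql_examples.namespaces import SH

__all__ = [
    "Severity",
    "ValidationIssue",
    "ValidationReport",
    "ProbeResult",
    "ISSUE_CODES",
    "validate_example",
    "validate_collection",
    "probe_example",
    "shapes_graph",
    "expand_query",
]

#: Closed set of issue codes.
ISSUE_CODES = frozenset(
    {
        "SYNTAX_ERROR",
        "MISSING_ID",
        "MISSING_TYPE",
        "MISSING_COMMENT",
        "MISSING_TARGET",
        "MISSING_LANGUAGE_TAG",
        "TYPE_QUERY_MISMATCH",
        "FEDERATED_WITHOUT_SERVICE",
        "UNDECLARED_FEDERATION",
        "DUPLICATE_ID",
        "LOAD_FAILURE",
    }
)


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass
class ValidationIssue:
    code: str
    severity: Severity
    subject: str
    message: str
    pointer: str = ""

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code: {self.code}")

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity.value,
            "subject": self.subject,
            "message": self.message,
            "pointer": self.pointer,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    examples_checked: int = 0

    @property
    def passed(self) -> bool:
        return not any(i.severity is Severity.ERROR for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.ERROR]

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)
        self.examples_checked += other.examples_checked

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "examples_checked": self.examples_checked,
                "issues": [i.to_dict() for i in self.issues],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"checked {self.examples_checked} example(s): "
            + ("PASS" if self.passed else f"FAIL ({len(self.errors())} error(s))")
        ]
        for issue in self.issues:
            lines.append(
                f"  [{issue.severity.value}] {issue.code} {issue.subject}: {issue.message}"
            )
        return "\n".join(lines)


def expand_query(example: ExampleDocument) -> str:
    """Query text with undeclared prefixes resolved from the document's map."""
    try:
        registry = PrefixRegistry.from_map(example.prefixes)
        return add_missing_prefixes(example.query_text, registry).fixed_query
    except Exception:
        return example.query_text  # unknown labels: let the parser report them


_FORM_TO_KIND = {
    "select": QueryKind.SELECT,
    "ask": QueryKind.ASK,
    "construct": QueryKind.CONSTRUCT,
    "describe": QueryKind.DESCRIBE,
}


def validate_example(example: ExampleDocument) -> ValidationReport:
    """Apply rules R1–R6 to one (possibly invariant-violating) document."""
    subject = example.identifier or "<no id>"
    issues: list[ValidationIssue] = []

    def issue(code: str, severity: Severity, message: str, pointer: str = "") -> None:
        issues.append(ValidationIssue(code, severity, subject, message, pointer))

    # R2: mandatory fields
    if example.identifier is None or not is_absolute_iri(example.identifier):
        issue("MISSING_ID", Severity.ERROR, "example has no absolute-IRI identifier", "identifier")
    if not example.declared_types:
        issue("MISSING_TYPE", Severity.ERROR, "example carries no rdf:type", "rdf:type")
    if not example.comments:
        issue("MISSING_COMMENT", Severity.ERROR, "no rdfs:comment question text", "rdfs:comment")
    if not example.targets:
        issue("MISSING_TARGET", Severity.ERROR, "no schema:target endpoint", "schema:target")

    # R3: language tag
    if example.comments and not any(lang for _, lang in example.comments):
        issue(
            "MISSING_LANGUAGE_TAG",
            Severity.ERROR,
            "no comment carries a language tag",
            "rdfs:comment",
        )

    # R1: strict syntax (grammar + algebra translation)
    parsed: _sparql.ParsedQuery | None = None
    expanded = expand_query(example)
    try:
        if example.kind is QueryKind.UPDATE:
            _sparql.strict_parse_update(expanded)
        else:
            parsed = _sparql.strict_parse(expanded)
    except QuerySyntaxError as exc:
        issue("SYNTAX_ERROR", Severity.ERROR, str(exc), "query")

    # R4: declared subtype vs query property vs parsed form
    expected_subtype = example.kind.shacl_subtype
    declared_subtypes = [
        t for t in example.declared_types if t != str(SH.SPARQLExecutable) and t.startswith(str(SH))
    ]
    if expected_subtype is None:
        if declared_subtypes:
            issue(
                "TYPE_QUERY_MISMATCH",
                Severity.ERROR,
                f"DESCRIBE example must be typed sh:SPARQLExecutable only, found {declared_subtypes}",
                "rdf:type",
            )
    elif declared_subtypes and str(expected_subtype) not in declared_subtypes:
        issue(
            "TYPE_QUERY_MISMATCH",
            Severity.ERROR,
            f"declared type(s) {declared_subtypes} do not match query property "
            f"for a {example.kind.value.upper()} query",
            "rdf:type",
        )
    if parsed is not None:
        form_kind = _FORM_TO_KIND.get(parsed.form)
        if form_kind is not None and form_kind is not example.kind:
            issue(
                "TYPE_QUERY_MISMATCH",
                Severity.ERROR,
                f"query property says {example.kind.value} but the text parses as {parsed.form}",
                "query",
            )

    # R5/R6: federation vs SERVICE (on the algebra, never on raw text)
    if parsed is not None:
        services = _sparql.service_endpoints(parsed.algebra)
        if example.declares_federation and not services:
            issue(
                "FEDERATED_WITHOUT_SERVICE",
                Severity.ERROR,
                "declared federated but the query contains no SERVICE clause",
                "query",
            )
        elif services and not example.declares_federation:
            issue(
                "UNDECLARED_FEDERATION",
                Severity.WARNING,
                f"query federates with {services} but is not declared federated",
                "spex:federatesWith",
            )

    return ValidationReport(issues=issues, examples_checked=1)


def validate_collection(collection: ExampleCollection) -> ValidationReport:
    """Union of per-example reports plus collection-level rules."""
    report = ValidationReport()
    for example in collection.examples:
        report.extend(validate_example(example))
    for identifier, first, second in collection.duplicates:
        report.issues.append(
            ValidationIssue(
                "DUPLICATE_ID",
                Severity.ERROR,
                identifier,
                f"identifier used by both {first} and {second}",
                "identifier",
            )
        )
    for path, message in collection.load_failures:
        report.issues.append(
            ValidationIssue("LOAD_FAILURE", Severity.ERROR, path, message, "file")
        )
    return report


# ---------------------------------------------------------------------------
# execution probes


@dataclass
class ProbeResult:
    """Outcome of executing an example with its result limit forced to 1."""

    outcome: str  # ok | empty | failed
    reason: str = ""
    rewritten_query: str = ""
    note: str | None = None


def probe_example(
    example: ExampleDocument,
    dataset: Graph | str | None = None,
    network_allowed: bool = False,
    timeout: float = 30.0,
) -> ProbeResult:
    """Execute an example against a local graph (or, opt-in, its endpoint).

    SELECT/CONSTRUCT/DESCRIBE queries are rewritten so their effective result
    limit is exactly 1 before execution, keeping probe load negligible; ASK
    queries run unchanged.  ``ok`` means at least one row/triple (or ``true``
    for ASK).  UPDATE examples are refused outright.  Remote execution happens
    only when ``network_allowed`` is true and ``dataset`` is an endpoint IRI.
    """
    if example.kind is QueryKind.UPDATE:
        raise UpdateQueryRefused("UPDATE examples are never executed by probes")

    query = expand_query(example)
    note = None
    if example.kind is not QueryKind.ASK:
        rewrite = _sparql.set_result_limit(query, 1)
        query, note = rewrite.query_text, rewrite.note

    if isinstance(dataset, str) or dataset is None:
        if not network_allowed:
            return ProbeResult("failed", "network disabled", query, note)
        endpoint = dataset or (example.targets[0] if example.targets else None)
        if endpoint is None:
            return ProbeResult("failed", "no endpoint to probe", query, note)
        return _remote_probe(endpoint, query, example.kind, note, timeout)

    try:
        parsed = _sparql.strict_parse(query)
    except QuerySyntaxError as exc:
        return ProbeResult("failed", f"query does not parse: {exc}", query, note)
    if _sparql.service_endpoints(parsed.algebra) and not network_allowed:
        return ProbeResult("failed", "network disabled", query, note)

    try:
        result = dataset.query(query)
    except Exception as exc:
        return ProbeResult("failed", f"execution error: {exc}", query, note)
    if example.kind is QueryKind.ASK:
        ok = bool(result.askAnswer)
    elif example.kind in (QueryKind.CONSTRUCT, QueryKind.DESCRIBE):
        ok = result.graph is not None and len(result.graph) > 0
    else:
        ok = any(True for _ in result)
    return ProbeResult("ok" if ok else "empty", "", query, note)


def _remote_probe(
    endpoint: str, query: str, kind: QueryKind, note: str | None, timeout: float
) -> ProbeResult:
    """POST the query to a remote endpoint (only reachable with network opt-in)."""
    from urllib.parse import urlencode

    accept = (
        "application/sparql-results+json"
        if kind in (QueryKind.SELECT, QueryKind.ASK)
        else "text/turtle"
    )
    request = Request(
        endpoint,
        data=urlencode({"query": query}).encode(),
        headers={
            "Accept": accept,
            "Content-Type": "application/x-www-form-urlencoded",
            "User-Agent": "sparql-examples-kit probe",
        },
    )
    try:
        with urlopen(request, timeout=timeout) as response:
            body = response.read()
    except Exception as exc:
        return ProbeResult("failed", f"endpoint error: {exc}", query, note)
    if kind is QueryKind.ASK:
        try:
            ok = bool(json.loads(body).get("boolean"))
        except Exception:
            return ProbeResult("failed", "unparseable ASK response", query, note)
    elif kind is QueryKind.SELECT:
        try:
            ok = bool(json.loads(body).get("results", {}).get("bindings"))
        except Exception:
            return ProbeResult("failed", "unparseable SELECT response", query, note)
    else:
        g = Graph()
        try:
            g.parse(data=body.decode("utf-8", "replace"), format="turtle")
        except Exception:
            return ProbeResult("failed", "unparseable graph response", query, note)
        ok = len(g) > 0
    return ProbeResult("ok" if ok else "empty", "", query, note)


def shapes_graph() -> Graph:
    """The SHACL shapes expressing the metadata rules, as an RDF graph."""
    text = (
        importlib_resources.files("sparql_examples")
        .joinpath("resources/example_shapes.ttl")
        .read_text(encoding="utf-8")
    )
    g = Graph()
    g.parse(data=text, format="turtle")
    return g
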