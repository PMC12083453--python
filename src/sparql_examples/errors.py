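"""Exception hierarchy shared across the toolkit."""


class SparqlExamplesError(Exception):
    """Base class for all errors raised by this package."""


class ExampleParseError(SparqlExamplesError):
    """Malformed Turtle in an example file (carries line info when known)."""


class ExampleStructureError(SparqlExamplesError):
    """A Turtle document that is not exactly one example subject."""


class MissingQueryError(ExampleStructureError):
    """An example subject without any query property (sh:select etc.)."""


class SerializationError(SparqlExamplesError):
    """Refusal to serialize a document that violates an invariant."""


class CollectionError(SparqlExamplesError):
    """A collection-level problem such as duplicate identifiers."""


class QuerySyntaxError(SparqlExamplesError):
    """SPARQL text rejected by the strict SPARQL 1.1 grammar."""


class AnalysisError(SparqlExamplesError):
    """A query that cannot be analyzed (it does not parse)."""


class GraphBuildError(SparqlExamplesError):
    """A query graph could not be constructed."""


class FixError(SparqlExamplesError):
    """A query repair stage failed."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message if stage is None else f"[{stage}] {message}")
        self.stage = stage


class UnknownPrefixError(FixError):
    """A prefix label used in a query is absent from the registry."""

    def __init__(self, label: str, stage: str | None = None):
        super().__init__(f"prefix label not in registry: {label!r}", stage)
        self.label = label


class UpdateQueryRefused(SparqlExamplesError):
    """UPDATE queries are never executed by probes."""


class FixtureSpecError(SparqlExamplesError):
    """An impossible synthetic-fixture specification."""
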