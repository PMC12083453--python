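"""Internal SPARQL helpers: strict parsing, algebra walks, text scanning.

The scanning helpers operate on a *masked* copy of the query text in which
string literals, comments and IRI references have been neutralized, so that
token-level rewrites (prefix injection, LIMIT override, hint stripping) never
misfire on the word ``SERVICE`` inside a literal or on a ``#`` inside an IRI.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

import pyparsing
from rdflib import URIRef, Variable
from rdflib.paths import AlternativePath, InvPath, MulPath, NegatedPath, Path, SequencePath
from rdflib.plugins.sparql.algebra import translateQuery, translateUpdate
from rdflib.plugins.sparql.parser import parseQuery, parseUpdate
from rdflib.plugins.sparql.parserutils import CompValue

from sparql_examples.errors import QuerySyntaxError

_IRIREF_RE = re.compile(r'<[^<>"{}|^`\\\x00-\x20]*>')

# ---------------------------------------------------------------------------
# text masking


def mask_query_text(text: str, mask_iris: bool = False) -> str:
    """Return ``text`` with strings, comments (and optionally IRIs) blanked.

    The result has the same length as the input; masked characters become
    spaces while all structural characters (braces, dots, keywords) survive,
    which makes position-based rewrites on the original text safe.
    """
    out = list(text)
    i, n = 0, len(text)

    def blank(a: int, b: int) -> None:
        for j in range(a, b):
            if out[j] not in "\r\n":
                out[j] = " "

    while i < n:
        c = text[i]
        if c == "<":
            m = _IRIREF_RE.match(text, i)
            if m:
                if mask_iris:
                    blank(i, m.end())
                i = m.end()
                continue
            i += 1
        elif c in "\"'":
            quote = text[i : i + 3] if text[i : i + 3] in ('"""', "'''") else c
            j = i + len(quote)
            while j < n:
                if text[j] == "\\":
                    j += 2
                    continue
                if text.startswith(quote, j):
                    j += len(quote)
                    break
                j += 1
            else:
                j = n
            blank(i + len(quote), j - len(quote))
            i = j
        elif c == "#":
            j = text.find("\n", i)
            j = n if j == -1 else j
            blank(i, j)
            i = j
        else:
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# strict parsing


@dataclass
class ParsedQuery:
    parse_tree: pyparsing.ParseResults
    query: object  # rdflib Query (holds .algebra)

    @property
    def algebra(self) -> CompValue:
        return self.query.algebra  # type: ignore[attr-defined]

    @property
    def form(self) -> str:
        """Query form: select, ask, construct or describe."""
        return {
            "SelectQuery": "select",
            "AskQuery": "ask",
            "ConstructQuery": "construct",
            "DescribeQuery": "describe",
        }[self.parse_tree[1].name]


def strict_parse(query_text: str) -> ParsedQuery:
    """Parse under the strict SPARQL 1.1 grammar, then translate to algebra.

    Both stages must succeed: the grammar stage catches token-level errors,
    the algebra translation stage catches structural ones (e.g. unbound
    aggregate projections).  Failures raise :class:`QuerySyntaxError`.
    """
    try:
        tree = parseQuery(query_text)
    except pyparsing.ParseException as exc:
        raise QuerySyntaxError(
            f"SPARQL grammar error at line {exc.lineno}, column {exc.column}: {exc.msg}"
        ) from exc
    try:
        query = translateQuery(tree)
    except Exception as exc:  # rdflib raises bare Exception for some cases
        raise QuerySyntaxError(f"SPARQL algebra error: {exc}") from exc
    return ParsedQuery(parse_tree=tree, query=query)


def strict_parse_update(update_text: str) -> object:
    """Parse a SPARQL UPDATE request; raise :class:`QuerySyntaxError` on failure."""
    try:
        tree = parseUpdate(update_text)
        return translateUpdate(tree)
    except pyparsing.ParseException as exc:
        raise QuerySyntaxError(
            f"SPARQL grammar error at line {exc.lineno}, column {exc.column}: {exc.msg}"
        ) from exc
    except Exception as exc:
        raise QuerySyntaxError(f"SPARQL algebra error: {exc}") from exc


# ---------------------------------------------------------------------------
# tree walking

_SEQUENCES = (list, tuple, set, pyparsing.ParseResults)


def walk_nodes(node: object) -> Iterator[CompValue]:
    """Yield every :class:`CompValue` in an algebra or parse tree, depth-first."""
    if isinstance(node, CompValue):
        yield node
        for value in node.values():
            yield from walk_nodes(value)
    elif isinstance(node, _SEQUENCES):
        for value in node:
            yield from walk_nodes(value)


def collect_triples(algebra: CompValue) -> list[tuple]:
    """All translated triple patterns anywhere in the algebra.

    Covers BGPs as well as the untranslated group patterns that rdflib keeps
    inside SERVICE and (NOT) EXISTS nodes, whose triples live in
    ``TriplesBlock`` values.
    """
    triples: list[tuple] = []
    for node in walk_nodes(algebra):
        if "triples" in node:
            for t in node["triples"]:
                if len(t) == 3:
                    triples.append(tuple(t))
    return triples


def decomposed_path_length(predicate: object) -> int:
    """Number of triple patterns a predicate stands for once paths decompose.

    Sequence paths of length *k* count as *k* patterns; an inverse path counts
    as its inner path; alternation, arbitrary-length (``*``, ``+``, ``?``) and
    negated property sets are not decomposable and count as one.
    """
    if isinstance(predicate, SequencePath):
        return sum(decomposed_path_length(p) for p in predicate.args)
    if isinstance(predicate, InvPath):
        return decomposed_path_length(predicate.arg)
    if isinstance(predicate, (MulPath, AlternativePath, NegatedPath)):
        return 1
    return 1


def service_endpoints(algebra: CompValue) -> list[str]:
    """SERVICE targets in document order; variable targets become "variable"."""
    endpoints: list[str] = []
    for node in walk_nodes(algebra):
        if node.name == "ServiceGraphPattern":
            term = node.get("term")
            if isinstance(term, URIRef):
                endpoints.append(str(term))
            elif isinstance(term, Variable):
                endpoints.append("variable")
    return endpoints


def is_path(predicate: object) -> bool:
    return isinstance(predicate, Path)


# ---------------------------------------------------------------------------
# LIMIT rewriting

_LIMIT_RE = re.compile(r"\bLIMIT\b[ \t]*(\d+)", re.IGNORECASE)


@dataclass
class LimitRewrite:
    query_text: str
    previous_limit: int | None  # None: no top-level LIMIT was present
    note: str | None = None


def set_result_limit(query_text: str, limit: int = 1) -> LimitRewrite:
    """Force the query's *top-level* result limit to ``limit``.

    A pre-existing top-level ``LIMIT n`` with ``n`` different from ``limit``
    is overridden — except ``LIMIT 0``, which is kept and flagged, since a
    deliberately empty query should not silently start returning rows.
    Limits inside subqueries are untouched.
    """
    masked = mask_query_text(query_text, mask_iris=True)
    depth = 0
    spans: list[tuple[int, int, int]] = []  # (start, end, value) at depth 0
    i = 0
    while i < len(masked):
        c = masked[i]
        if c == "{":
            depth += 1
        elif c == "}":
            depth -= 1
        elif depth == 0 and c in "Ll":
            m = _LIMIT_RE.match(masked, i)
            if m:
                spans.append((m.start(), m.end(), int(m.group(1))))
                i = m.end()
                continue
        i += 1

    if not spans:
        return LimitRewrite(query_text.rstrip() + f"\nLIMIT {limit}", None)
    start, end, value = spans[-1]
    if value == 0:
        return LimitRewrite(query_text, 0, "existing LIMIT 0 kept")
    if value == limit:
        return LimitRewrite(query_text, value)
    return LimitRewrite(query_text[:start] + f"LIMIT {limit}" + query_text[end:], value)
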