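"""Rewrite queries using vendor extensions into strict SPARQL 1.1.

Three repairs are applied, in a fixed pipeline order:

1. **Missing prefix injection** — prefix labels used in prefixed names but
   never declared are resolved against a registry of common (plus optional
   project-specific) prefixes and prepended as ``PREFIX`` lines.  This stage
   works on raw tokens because a missing prefix makes the query unparseable
   in the first place.
2. **Named-subquery inlining** — the Blazegraph/Anzo extension
   ``WITH { <subselect> } AS %name`` … ``INCLUDE %name`` (widespread in the
   Wikidata community) is rewritten into standard nested subselects; each
   ``INCLUDE`` is replaced in place by the braced subselect, duplicating it
   when included more than once.
3. **Hint stripping** — "magic triples" carrying engine execution hints
   (Blazegraph ``hint:``, Neptune query hints) match no data on other stores
   and would make queries return empty results; any triple pattern whose
   subject or predicate falls in a configured hint namespace is removed.

Every result is guaranteed to parse under the strict SPARQL 1.1 grammar, and
the pipeline is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from sparql_examples._sparql import mask_query_text, strict_parse, strict_parse_update
from sparql_examples.errors import FixError, QuerySyntaxError, UnknownPrefixError
from sparql_examples.example_model import PrefixMap

__all__ = [
    "AppliedFix",
    "FixResult",
    "PrefixRegistry",
    "DEFAULT_COMMON_PREFIXES",
    "DEFAULT_HINT_NAMESPACES",
    "add_missing_prefixes",
    "rewrite_named_subqueries",
    "strip_query_hints",
    "fix_query",
]

#: Widely used prefixes across bioinformatics SPARQL endpoints.
DEFAULT_COMMON_PREFIXES: dict[str, str] = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "sh": "http://www.w3.org/ns/shacl#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "schema": "https://schema.org/",
    "dcterms": "http://purl.org/dc/terms/",
    "foaf": "http://xmlns.com/foaf/0.1/",
    "void": "http://rdfs.org/ns/void#",
    "sd": "http://www.w3.org/ns/sparql-service-description#",
    "up": "http://purl.uniprot.org/core/",
    "taxon": "http://purl.uniprot.org/taxonomy/",
    "uniprotkb": "http://purl.uniprot.org/uniprot/",
    "rh": "http://rdf.rhea-db.org/",
    "genex": "http://purl.org/genex#",
    "orth": "http://purl.org/net/orth#",
    "sio": "http://semanticscience.org/resource/",
    "obo": "http://purl.obolibrary.org/obo/",
    "wd": "http://www.wikidata.org/entity/",
    "wdt": "http://www.wikidata.org/prop/direct/",
    "wikibase": "http://wikiba.se/ontology#",
    "bd": "http://www.bigdata.com/rdf#",
    "hint": "http://www.bigdata.com/queryHints#",
    "spex": "https://purl.expasy.org/sparql-examples/ontology#",
}

#: Engine-hint namespaces stripped by default (Blazegraph, AWS Neptune).
DEFAULT_HINT_NAMESPACES: list[str] = [
    "http://www.bigdata.com/queryHints#",
    "http://aws.amazon.com/neptune/vocab/v01/QueryHints#",
]


@dataclass
class PrefixRegistry:
    """Common prefixes plus an optional project-specific overlay.

    Overlay entries shadow common entries on label collision.
    """

    common: PrefixMap = field(default_factory=lambda: PrefixMap(DEFAULT_COMMON_PREFIXES))
    overlay: PrefixMap | None = None

    def lookup(self, label: str) -> str | None:
        if self.overlay is not None:
            ns = self.overlay.get(label)
            if ns is not None:
                return ns
        return self.common.get(label)

    @classmethod
    def from_map(cls, prefixes: PrefixMap, include_common: bool = True) -> "PrefixRegistry":
        if include_common:
            return cls(overlay=prefixes)
        return cls(common=prefixes, overlay=None)

    @classmethod
    def from_file(cls, path: str | Path, include_common: bool = True) -> "PrefixRegistry":
        """Read ``label<whitespace>namespace`` lines (``#`` comments allowed)."""
        overlay = PrefixMap()
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise FixError(f"bad registry line: {raw!r}", stage="prefixes")
            label = parts[0].rstrip(":")
            overlay.add(label, parts[1].strip().strip("<>"))
        if include_common:
            return cls(overlay=overlay)
        return cls(common=overlay, overlay=None)


@dataclass
class AppliedFix:
    """One applied repair: code in {PREFIX_ADDED, NAMED_SUBQUERY_INLINED, HINT_REMOVED}."""

    code: str
    detail: str

    def __str__(self) -> str:
        return f"{self.code}({self.detail})"


@dataclass
class FixResult:
    fixed_query: str
    applied_fixes: list[AppliedFix] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def changed(self) -> bool:
        return bool(self.applied_fixes)


# ---------------------------------------------------------------------------
# stage 1: prefixes

_PREFIX_DECL_RE = re.compile(r"(?i)\bPREFIX\s+([^\s:]*):")
# A prefixed-name occurrence: label ':' followed by a local-name character or
# whitespace/delimiter is still a valid pname (e.g. "rdf:" alone).  The label
# must not be preceded by a character that would make it part of another token.
_PNAME_RE = re.compile(r"(?<![\w?$:<\-])([A-Za-z][\w.\-]*)?:(?!//)")


def _used_prefix_labels(masked: str) -> list[str]:
    """Prefix labels used in prefixed names, in first-use order."""
    decl_spans = [m.span() for m in _PREFIX_DECL_RE.finditer(masked)]
    labels: list[str] = []
    for m in _PNAME_RE.finditer(masked):
        if any(a <= m.start() < b for a, b in decl_spans):
            continue
        label = m.group(1) or ""
        if label not in labels:
            labels.append(label)
    return labels


def add_missing_prefixes(query_text: str, registry: PrefixRegistry | None = None) -> FixResult:
    """Prepend ``PREFIX`` declarations for used-but-undeclared labels.

    Operates on tokens, not the parse tree, because the missing declarations
    themselves make the query unparseable.  Raises
    :class:`UnknownPrefixError` when a label is absent from the registry.
    """
    registry = registry or PrefixRegistry()
    masked = mask_query_text(query_text, mask_iris=True)
    declared = {m.group(1) for m in _PREFIX_DECL_RE.finditer(masked)}
    missing = [label for label in _used_prefix_labels(masked) if label not in declared]
    if not missing:
        return FixResult(query_text)
    lines = []
    fixes = []
    for label in missing:
        namespace = registry.lookup(label)
        if namespace is None:
            raise UnknownPrefixError(label, stage="prefixes")
        lines.append(f"PREFIX {label}: <{namespace}>")
        fixes.append(AppliedFix("PREFIX_ADDED", label))
    return FixResult("\n".join(lines) + "\n" + query_text, fixes)


# ---------------------------------------------------------------------------
# stage 2: named subqueries

_WITH_RE = re.compile(r"(?i)\bWITH\b")
_AS_NAME_RE = re.compile(r"(?i)\s*AS\s+%(\w+)")
_INCLUDE_RE = re.compile(r"(?i)\bINCLUDE\s+%(\w+)")


def _matching_brace(text: str, masked: str, start: int) -> int:
    """Index just past the brace matching ``masked[start] == '{'``."""
    depth = 0
    for i in range(start, len(masked)):
        if masked[i] == "{":
            depth += 1
        elif masked[i] == "}":
            depth -= 1
            if depth == 0:
                return i + 1
    raise FixError("unbalanced braces in named subquery", stage="named-subqueries")


def rewrite_named_subqueries(query_text: str) -> FixResult:
    """Inline ``WITH {…} AS %name`` blocks at their ``INCLUDE %name`` sites."""
    masked = mask_query_text(query_text, mask_iris=True)
    blocks: dict[str, str] = {}
    removals: list[tuple[int, int]] = []
    for m in _WITH_RE.finditer(masked):
        brace = masked.find("{", m.end())
        if brace == -1 or masked[m.end() : brace].strip():
            continue  # WITH not followed by a block (not the extension syntax)
        end = _matching_brace(query_text, masked, brace)
        name_match = _AS_NAME_RE.match(masked, end)
        if not name_match:
            continue
        blocks[name_match.group(1)] = query_text[brace:end]
        removals.append((m.start(), name_match.end()))
    if not blocks and not _INCLUDE_RE.search(masked):
        return FixResult(query_text)

    used: set[str] = set()
    for m in _INCLUDE_RE.finditer(masked):
        name = m.group(1)
        if name not in blocks:
            raise FixError(f"INCLUDE of undefined named subquery %{name}", stage="named-subqueries")
        used.add(name)

    pieces: list[str] = []
    pos = 0
    for start, end in removals:
        pieces.append(query_text[pos:start])
        pos = end
    pieces.append(query_text[pos:])
    stripped = "".join(pieces)

    def _inline(match: re.Match) -> str:
        return blocks[match.group(1)]

    fixed = _INCLUDE_RE.sub(_inline, stripped)
    fixes = [AppliedFix("NAMED_SUBQUERY_INLINED", name) for name in sorted(blocks)]
    warnings = [
        f"named subquery %{name} declared but never included; dropped"
        for name in sorted(set(blocks) - used)
    ]
    return FixResult(fixed, fixes, warnings)


# ---------------------------------------------------------------------------
# stage 3: hint stripping


def _declared_prefixes(query_text: str) -> dict[str, str]:
    decls = {}
    for m in re.finditer(r"(?i)\bPREFIX\s+([^\s:]*):\s*<([^>]*)>", query_text):
        decls[m.group(1)] = m.group(2)
    return decls


def _term_iri(token: str, prefixes: dict[str, str]) -> str | None:
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    m = re.match(r"^([A-Za-z][\w.\-]*)?:(\S*)$", token)
    if m:
        ns = prefixes.get(m.group(1) or "")
        if ns is not None:
            return ns + m.group(2)
    return None


def strip_query_hints(
    query_text: str, hint_namespaces: list[str] | None = None
) -> FixResult:
    """Remove "magic" hint triples (subject or predicate in a hint namespace).

    Raises :class:`FixError` if removal would leave an empty WHERE pattern
    (the query consisted of nothing but hints).
    """
    from sparql_examples._sparql import _IRIREF_RE

    namespaces = DEFAULT_HINT_NAMESPACES if hint_namespaces is None else list(hint_namespaces)
    # strings/comments are masked; IRIs stay visible but are skipped
    # atomically so a dot inside an IRI never terminates a statement
    masked = mask_query_text(query_text)
    prefixes = _declared_prefixes(query_text)

    def in_hint_ns(iri: str | None) -> bool:
        return iri is not None and any(iri.startswith(ns) for ns in namespaces)

    # Statement spans inside group graph patterns: from the end of the
    # previous '{' / '.' / '}' boundary to the terminating '.' (or the brace).
    removals: list[tuple[int, int]] = []
    count = 0
    depth = 0
    i = 0
    while i < len(masked):
        c = masked[i]
        if c == "{":
            depth += 1
            i += 1
            continue
        if c == "}":
            depth -= 1
            i += 1
            continue
        if depth == 0 or c.isspace() or c == ".":
            i += 1
            continue
        # start of a statement: find its end at this depth
        stmt_start = i
        inner = 0
        end = i
        while end < len(masked):
            ch = masked[end]
            if ch == "<":
                iri_match = _IRIREF_RE.match(masked, end)
                if iri_match:
                    end = iri_match.end()
                    continue
            if ch == "{":
                inner += 1
            elif ch == "}":
                if inner == 0:
                    break
                inner -= 1
            elif ch == "." and inner == 0:
                end += 1
                break
            end += 1
        tokens = query_text[stmt_start:end].split()
        subj_iri = _term_iri(tokens[0], prefixes) if tokens else None
        pred_iri = _term_iri(tokens[1], prefixes) if len(tokens) > 1 else None
        if in_hint_ns(subj_iri) or in_hint_ns(pred_iri):
            removals.append((stmt_start, end))
            count += 1
        i = end if end > i else i + 1

    if not removals:
        return FixResult(query_text)
    out = []
    pos = 0
    for start, end in removals:
        out.append(query_text[pos:start])
        pos = end
    out.append(query_text[pos:])
    fixed = "".join(out)
    fixed_masked = mask_query_text(fixed, mask_iris=True)
    for m in re.finditer(r"(?i)\bWHERE\s*{([^{}]*)}", fixed_masked):
        if not m.group(1).strip():
            raise FixError("stripping hints left an empty WHERE pattern", stage="hints")
    return FixResult(fixed, [AppliedFix("HINT_REMOVED", str(count))])


# ---------------------------------------------------------------------------
# full pipeline


def _is_update_text(query_text: str) -> bool:
    masked = mask_query_text(query_text, mask_iris=True)
    return bool(
        re.search(r"(?i)\b(INSERT|DELETE|LOAD|CLEAR|DROP|CREATE|MOVE|COPY|ADD)\b", masked)
    ) and not re.search(r"(?i)\b(SELECT|ASK|CONSTRUCT|DESCRIBE)\b", masked)


def fix_query(
    query_text: str,
    registry: PrefixRegistry | None = None,
    hint_namespaces: list[str] | None = None,
) -> FixResult:
    """Run the full repair pipeline: prefixes → named subqueries → hints.

    The returned query is guaranteed to parse under the strict SPARQL 1.1
    grammar; stage errors propagate annotated with their stage name.
    """
    fixes: list[AppliedFix] = []
    warnings: list[str] = []

    step = add_missing_prefixes(query_text, registry)
    fixes += step.applied_fixes
    step2 = rewrite_named_subqueries(step.fixed_query)
    fixes += step2.applied_fixes
    warnings += step2.warnings
    step3 = strip_query_hints(step2.fixed_query, hint_namespaces)
    fixes += step3.applied_fixes

    fixed = step3.fixed_query
    try:
        if _is_update_text(fixed):
            strict_parse_update(fixed)
        else:
            strict_parse(fixed)
    except QuerySyntaxError as exc:
        raise FixError(f"result does not parse: {exc}", stage="final-check") from exc
    if not fixes:
        return FixResult(query_text, [], warnings)
    return FixResult(fixed, fixes, warnings)
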