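"""Query-graph construction and Mermaid/Markdown rendering.

A query's triple patterns become a labeled directed graph: variables,
IRIs and literals are nodes, predicates are numbered edge labels, and
sequence property paths are decomposed into chains through anonymous
intermediary nodes (rendered as small circles).  Projected variables get a
distinct style so a reader can see at a glance what the query returns.
Edges contributed by OPTIONAL / UNION / MINUS / subquery patterns are drawn
dashed with a context tag; SERVICE bodies are grouped into a subgraph naming
the remote endpoint.  The edge numbering matches the triple-pattern counting
convention of :mod:`~sparql_examples.query_analysis`, so diagram size and TP
count always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdflib import BNode, Literal, URIRef, Variable
from rdflib.namespace import RDF
from rdflib.paths import AlternativePath, InvPath, MulPath, NegatedPath, SequencePath
from rdflib.plugins.sparql.parserutils import CompValue

from sparql_examples import _sparql
from sparql_examples.errors import GraphBuildError, QuerySyntaxError
from sparql_examples.example_model import ExampleCollection, ExampleDocument, PrefixMap
from sparql_examples.fixer import DEFAULT_COMMON_PREFIXES, PrefixRegistry, add_missing_prefixes

__all__ = [
    "QueryGraph",
    "GraphNode",
    "GraphEdge",
    "MermaidDocument",
    "build_query_graph",
    "render_mermaid",
    "render_markdown_page",
    "render_collection",
]

_LITERAL_MAX = 30


@dataclass
class GraphNode:
    id: str
    role: str  # variable | iri | literal | anonymous
    label: str


@dataclass
class GraphEdge:
    ordinal: int
    subject: str
    predicate: str
    object: str
    context: str = "base"  # base | optional | union | minus | subquery | service <iri>


@dataclass
class QueryGraph:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)
    projected: set[str] = field(default_factory=set)

    def node(self, node_id: str) -> GraphNode | None:
        for n in self.nodes:
            if n.id == node_id:
                return n
        return None


@dataclass
class MermaidDocument:
    text: str
    direction: str = "TD"


def _display_prefixes(query_text: str, prefixes: PrefixMap | None) -> PrefixMap:
    """CURIE display map: common prefixes, the document's map, and the
    query's own PREFIX declarations (highest precedence)."""
    from sparql_examples.fixer import _declared_prefixes

    merged = PrefixMap(DEFAULT_COMMON_PREFIXES)
    if prefixes is not None:
        merged = merged.merged(prefixes)
    declared = PrefixMap()
    for label, namespace in sorted(_declared_prefixes(query_text).items()):
        try:
            declared.add(label, namespace)
        except ValueError:
            continue
    return merged.merged(declared)


class _GraphBuilder:
    def __init__(self, prefixes: PrefixMap):
        self.prefixes = prefixes
        self.graph = QueryGraph()
        self._ids: dict[object, str] = {}
        self._taken: set[str] = set()
        self._anon_counter = 0
        self._seen_top_project = False

    # -- node handling ----------------------------------------------------

    def _sanitize(self, text: str) -> str:
        out = []
        for ch in text:
            out.append(ch if ch.isalnum() or ch == "_" else f"_x{ord(ch):02x}")
        ident = "".join(out) or "_"
        if ident[0].isdigit():
            ident = "_" + ident
        return ident

    def _unique(self, candidate: str) -> str:
        ident, n = candidate, 1
        while ident in self._taken:
            n += 1
            ident = f"{candidate}_{n}"
        self._taken.add(ident)
        return ident

    def _curie(self, iri: URIRef) -> str:
        return self.prefixes.curie(str(iri)) or f"<{iri}>"

    def node_for(self, term: object) -> str:
        if term in self._ids:
            return self._ids[term]
        if isinstance(term, Variable):
            node = GraphNode(self._unique("v_" + self._sanitize(str(term))), "variable", f"?{term}")
        elif isinstance(term, URIRef):
            node = GraphNode(self._unique("i_" + self._sanitize(self._curie(term))), "iri", self._curie(term))
        elif isinstance(term, Literal):
            text = str(term)
            label = text if len(text) <= _LITERAL_MAX else text[: _LITERAL_MAX - 1] + "…"
            node = GraphNode(self._unique("l_" + self._sanitize(text[:16])), "literal", label)
        elif isinstance(term, BNode):
            node = GraphNode(self._unique("b_" + self._sanitize(str(term))), "anonymous", " ")
        else:
            node = GraphNode(self._unique("t_" + self._sanitize(str(term))), "literal", str(term))
        self._ids[term] = node.id
        self.graph.nodes.append(node)
        return node.id

    def fresh_anonymous(self) -> str:
        self._anon_counter += 1
        node = GraphNode(self._unique(f"_anon{self._anon_counter}"), "anonymous", " ")
        self.graph.nodes.append(node)
        return node.id

    # -- edge handling -----------------------------------------------------

    def path_label(self, path: object) -> str:
        if isinstance(path, URIRef):
            return "a" if path == RDF.type else self._curie(path)
        if isinstance(path, Variable):
            return f"?{path}"
        if isinstance(path, SequencePath):
            return "/".join(self.path_label(p) for p in path.args)
        if isinstance(path, InvPath):
            return "^" + self.path_label(path.arg)
        if isinstance(path, MulPath):
            return self.path_label(path.path) + path.mod
        if isinstance(path, AlternativePath):
            return "|".join(self.path_label(p) for p in path.args)
        if isinstance(path, NegatedPath):
            return "!(" + "|".join(self.path_label(p) for p in path.args) + ")"
        return str(path)

    def emit_edge(self, subj_id: str, label: str, obj_id: str, context: str) -> None:
        self.graph.edges.append(
            GraphEdge(len(self.graph.edges) + 1, subj_id, label, obj_id, context)
        )

    def emit_triple(self, subject: object, predicate: object, obj: object, context: str) -> None:
        """Decompose the predicate and emit one edge per resulting pattern."""
        if isinstance(predicate, SequencePath):
            parts = list(predicate.args)
            left = subject
            for index, part in enumerate(parts):
                last = index == len(parts) - 1
                right: object | str = obj if last else self.fresh_anonymous()
                self._emit_part(left, part, right, context)
                left = right
        elif isinstance(predicate, InvPath):
            self.emit_triple(obj, predicate.arg, subject, context)
        else:
            self.emit_edge(
                self._resolve(subject), self.path_label(predicate), self._resolve(obj), context
            )

    def _emit_part(self, left: object, part: object, right: object, context: str) -> None:
        """Emit one segment of a sequence path; segment endpoints may be node ids."""
        if isinstance(part, SequencePath):
            parts = list(part.args)
            for index, sub in enumerate(parts):
                last = index == len(parts) - 1
                mid: object | str = right if last else self.fresh_anonymous()
                self._emit_part(left, sub, mid, context)
                left = mid
        elif isinstance(part, InvPath):
            self._emit_part(right, part.arg, left, context)
        else:
            self.emit_edge(self._resolve(left), self.path_label(part), self._resolve(right), context)

    def _resolve(self, term: object) -> str:
        # rdflib terms subclass str, so check for them before plain node ids
        if isinstance(term, (Variable, URIRef, Literal, BNode)):
            return self.node_for(term)
        return str(term)

    # -- algebra walk ------------------------------------------------------

    def walk(self, node: object, context: str) -> None:
        if isinstance(node, CompValue):
            name = node.name
            if name == "ServiceGraphPattern":
                term = node.get("term")
                endpoint = str(term) if isinstance(term, URIRef) else "?" + str(term)
                self.walk(node.get("graph"), f"service {endpoint}")
                return
            if name == "LeftJoin":
                self.walk(node.get("p1"), context)
                self.walk(node.get("p2"), "optional")
                self.walk(node.get("expr"), context)
                return
            if name in ("Union", "GroupOrUnionGraphPattern"):
                members = (
                    [node.get("p1"), node.get("p2")]
                    if name == "Union"
                    else list(node.get("graph", []))
                )
                for member in members:
                    self.walk(member, "union" if len(members) > 1 else context)
                return
            if name == "Minus":
                self.walk(node.get("p1"), context)
                self.walk(node.get("p2"), "minus")
                return
            if name == "OptionalGraphPattern":  # inside untranslated SERVICE bodies
                for value in node.values():
                    self.walk(value, "optional")
                return
            if name == "Project":
                inner_context = context
                if self._seen_top_project:
                    inner_context = "subquery"
                self._seen_top_project = True
                for value in node.values():
                    self.walk(value, inner_context)
                return
            if "triples" in node:
                for t in node["triples"]:
                    if len(t) == 3:
                        self.emit_triple(t[0], t[1], t[2], context)
            for key, value in node.items():
                if key != "triples":
                    self.walk(value, context)
        elif isinstance(node, (list, tuple)):
            for value in node:
                self.walk(value, context)


def build_query_graph(query_text: str, prefixes: PrefixMap | None = None) -> QueryGraph:
    """Build the :class:`QueryGraph` of a query.

    Anonymous-node identifiers come from a counter in pattern order, so the
    output (and everything rendered from it) is deterministic.
    """
    display = _display_prefixes(query_text, prefixes)
    text = query_text
    if prefixes is not None and len(prefixes):
        try:
            text = add_missing_prefixes(query_text, PrefixRegistry.from_map(prefixes)).fixed_query
        except Exception:
            pass
    try:
        parsed = _sparql.strict_parse(text)
    except QuerySyntaxError as exc:
        raise GraphBuildError(str(exc)) from exc

    builder = _GraphBuilder(display)
    if parsed.form != "select":
        builder._seen_top_project = True  # any Project below is a subquery
    builder.walk(parsed.algebra, "base")

    if parsed.form == "select":
        for variable in parsed.algebra.get("PV", []):
            node_id = builder._ids.get(variable)
            if node_id is not None:
                builder.graph.projected.add(node_id)
    return builder.graph


# ---------------------------------------------------------------------------
# Mermaid rendering


def _mermaid_escape(text: str) -> str:
    return text.replace('"', "#quot;")


def _node_statement(node: GraphNode) -> str:
    label = _mermaid_escape(node.label)
    if node.role == "anonymous":
        return f'{node.id}((" "))'
    if node.role == "iri":
        return f'{node.id}(["{label}"])'
    return f'{node.id}["{label}"]'


def render_mermaid(graph: QueryGraph, direction: str = "TD") -> MermaidDocument:
    """Render a :class:`QueryGraph` as a Mermaid ``graph`` diagram.

    Projected variables carry the ``projected`` style class (drawn green);
    OPTIONAL/UNION/MINUS/subquery edges are dashed and tagged; SERVICE edges
    are placed in a subgraph labeled with the remote endpoint.
    """
    lines = [f"graph {direction}"]
    for node in graph.nodes:
        lines.append("  " + _node_statement(node))

    def edge_statement(edge: GraphEdge) -> str:
        label = f"{edge.ordinal}. {_mermaid_escape(edge.predicate)}"
        if edge.context in ("optional", "union", "minus", "subquery"):
            return f'  {edge.subject} -. "{label} [{edge.context}]" .-> {edge.object}'
        return f'  {edge.subject} -- "{label}" --> {edge.object}'

    service_groups: dict[str, list[GraphEdge]] = {}
    for edge in graph.edges:
        if edge.context.startswith("service "):
            service_groups.setdefault(edge.context[len("service ") :], []).append(edge)
        else:
            lines.append(edge_statement(edge))
    for index, (endpoint, edges) in enumerate(service_groups.items()):
        lines.append(f'  subgraph service{index}["SERVICE {_mermaid_escape(endpoint)}"]')
        for edge in edges:
            lines.append("  " + edge_statement(edge))
        lines.append("  end")

    lines.append("  classDef projected fill:#c6e48b,stroke:#2e7d32;")
    lines.append("  classDef anonymous fill:#eeeeee,stroke:#999999;")
    if graph.projected:
        lines.append("  class " + ",".join(sorted(graph.projected)) + " projected;")
    anonymous = [n.id for n in graph.nodes if n.role == "anonymous"]
    if anonymous:
        lines.append("  class " + ",".join(anonymous) + " anonymous;")
    return MermaidDocument("\n".join(lines) + "\n", direction)


# ---------------------------------------------------------------------------
# Markdown pages


def _page_title(example: ExampleDocument) -> str:
    if example.identifier:
        tail = example.identifier.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
        return tail or example.identifier
    return "example"


def render_markdown_page(example: ExampleDocument) -> str:
    """One Markdown page: questions, metadata, Mermaid diagram, query text."""
    parts = [f"# {_page_title(example)}", ""]
    for text, lang in example.comments:
        tag = f" `@{lang}`" if lang else ""
        parts.append(f"**{text}**{tag}")
        parts.append("")
    if example.keywords:
        parts.append("Keywords: " + ", ".join(f"`{k}`" for k in example.keywords))
        parts.append("")
    if example.targets:
        parts.append("Target endpoints:")
        parts.extend(f"- <{t}>" for t in example.targets)
        parts.append("")
    if example.federates_with:
        parts.append("Federates with:")
        parts.extend(f"- <{t}>" for t in example.federates_with)
        parts.append("")
    try:
        graph = build_query_graph(example.query_text, example.prefixes)
        parts.append("```mermaid")
        parts.append(render_mermaid(graph).text.rstrip("\n"))
        parts.append("```")
    except GraphBuildError as exc:
        parts.append(f"> Diagram unavailable: {exc}")
    parts.append("")
    parts.append("```sparql")
    parts.append(example.query_text.rstrip("\n"))
    parts.append("```")
    parts.append("")
    return "\n".join(parts)


def render_collection(collection: ExampleCollection, out_dir: str | Path) -> list[Path]:
    """Write one Markdown page per example plus an index, mirroring resources."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    index: dict[str, list[tuple[str, str]]] = {}
    for example in collection.examples:
        identifier = example.identifier or ""
        resource = collection.resource_of.get(identifier, "")
        source = collection.source_of.get(identifier)
        stem = Path(source).stem if source else _page_title(example)
        folder = out / resource if resource else out
        folder.mkdir(parents=True, exist_ok=True)
        page = folder / f"{stem}.md"
        page.write_text(render_markdown_page(example), encoding="utf-8")
        written.append(page)
        link = f"{resource}/{stem}.md" if resource else f"{stem}.md"
        question = example.question() or stem
        index.setdefault(resource, []).append((question, link))

    lines = ["# SPARQL example queries", ""]
    for resource in sorted(index):
        lines.append(f"## {resource or 'examples'}")
        lines.append("")
        for question, link in sorted(index[resource], key=lambda pair: pair[1]):
            lines.append(f"- [{question}]({link})")
        lines.append("")
    index_page = out / "index.md"
    index_page.write_text("\n".join(lines), encoding="utf-8")
    written.append(index_page)
    return written
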