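# Methods

This note documents the conventions, numerical choices and known limitations
behind the toolkit. It is written for maintainers adopting the example
representation for their own knowledge graphs.

## The example model

An example document is a single RDF subject carrying: a query property
(`sh:select`, `sh:ask`, `sh:construct`, `sh:update` or `spex:describe`), one
or more `rdfs:comment` questions (at least one language-tagged), one or more
`schema:target` endpoints, optional `schema:keywords`, an optional
`sh:prefixes` node with `sh:declare` declarations, and optional
`spex:federatesWith` endpoints. The SHACL subtype mirrors the query form;
DESCRIBE queries, which SHACL cannot represent, are typed plain
`sh:SPARQLExecutable` and use the extension property `spex:describe`.

Design choices that the vocabulary leaves open:

* **One query per file.** A subject with two query properties, or a file
  with two example subjects, is a structure error rather than a multi-query
  document. This keeps file ↔ example ↔ identifier a bijection.
* **Shared prefixes.** A file may reference a prefixes node it does not
  define. At collection load, the node is resolved from a `prefixes.ttl`
  file in the same resource folder; declarations found in the file itself
  take precedence.
* **Keyword literals are preserved verbatim** (including, e.g., trailing
  punctuation); normalization is the consumer's concern.
* **Federation declaration.** A query counts as declared-federated when it
  has `spex:federatesWith` triples or the keyword `federated`.
* Both `https://schema.org/` and the legacy `http://schema.org/` namespace
  are accepted on input; output uses the https form.

## Validation

Six rules per example. R1 (syntax) runs the strict SPARQL 1.1 grammar parse
*and* the algebra translation as two stages — an approximation of checking
with two independent parser implementations using one parser library; the
translation stage catches structural errors (e.g. aggregate misuse) that the
grammar alone admits. R2–R4 cover mandatory fields, language tags and
type/query agreement; the same constraints are shipped as SHACL shapes
(`resources/example_shapes.ttl`) for external SHACL engines, while this
package evaluates them natively. R5/R6 relate federation declarations to
SERVICE clauses; detection works on the parsed algebra, never on raw text,
so the word "SERVICE" inside a string literal cannot trigger it. A SERVICE
clause without a declaration is a *warning* (the converse, a declaration
without SERVICE, is an error): undeclared federation is a metadata gap, not
a broken example.

Issue codes form a closed set: `SYNTAX_ERROR`, `MISSING_ID`, `MISSING_TYPE`,
`MISSING_COMMENT`, `MISSING_TARGET`, `MISSING_LANGUAGE_TAG`,
`TYPE_QUERY_MISMATCH`, `FEDERATED_WITHOUT_SERVICE`,
`UNDECLARED_FEDERATION` (warning), `DUPLICATE_ID`, `LOAD_FAILURE`.

### Execution probes

Probes answer "does this example still return anything?" while keeping load
on the queried store negligible: SELECT/CONSTRUCT/DESCRIBE queries are
rewritten so their **top-level result limit is exactly 1** before execution.
A larger pre-existing limit is overridden; `LIMIT 0` is kept and flagged (a
deliberately empty query should not silently start returning rows); limits
inside subqueries are untouched. ASK queries run unchanged; UPDATE examples
are refused outright. The rewrite is token-based over a masked copy of the
query (strings, comments and IRIs are neutralized), so `"LIMIT 99"` inside a
literal is never touched. Remote probes are off by default and never run
without an explicit network opt-in; with networking disabled, queries
containing SERVICE are reported `failed: network disabled` rather than
silently executed half-locally.

## Complexity metrics

The central statistic is the triple-pattern (TP) count, a proxy for join
hops. Convention (applied uniformly by the analyzer and the visualizer):

* Basic triple patterns are counted in **all** group graph patterns:
  OPTIONAL, UNION branches, MINUS, subqueries, SERVICE bodies, and
  (NOT) EXISTS filter bodies.
* A sequence property path `p1/p2/…/pk` counts as *k* patterns, matching its
  decomposition into *k* joins. Inverse wrappers (`^p`) do not change the
  count of their inner path. Alternation, `*`/`+`/`?` and negated property
  sets are not decomposable and count as 1.
* VALUES contributes 0 (it does not traverse the graph).

Aggregate applications (`COUNT`, `SUM`, `AVG`, `MIN`, `MAX`, `GROUP_CONCAT`,
`SAMPLE`) are counted wherever they appear — projection, HAVING, subqueries —
on a fresh parse tree, because algebra translation inserts implicit SAMPLE
nodes for non-grouped projections (not written by the author) and consumes
HAVING clauses.

Per-endpoint statistics keep exact rational means internally and round to
one decimal only for display. An example with several targets contributes to
every target's row, so endpoint rows sum to examples-times-targets, not to
the collection size.

## Visualization

Each query becomes a directed labeled graph: one edge per (decomposed)
triple pattern, numbered consecutively in emission order so diagram edges can
be matched to query patterns. Sequence paths thread through fresh anonymous
nodes `_anon1, _anon2, …` (counter-based, never random, so output is
byte-reproducible); inverse paths flip edge direction; non-decomposable paths
become one edge labeled with the path expression. IRIs display as CURIEs
when a prefix is known (from a built-in common set, the document's prefix
map, and the query's own declarations); `rdf:type` displays as `a`.
Projected variables carry a `projected` style class (green); anonymous nodes
render as small gray circles. OPTIONAL/UNION/MINUS/subquery edges are drawn
dashed with a context tag rather than as nested subgraphs — only SERVICE
bodies get a subgraph, labeled with the remote endpoint — a legibility
trade-off, since Mermaid nests poorly. Node identifiers are sanitized by
hex-escaping non-alphanumerics, with collision suffixes keeping the mapping
injective per document. Literal labels are truncated at 30 characters.

Edge order follows rdflib's algebra ordering, which is deterministic for a
given query but may differ from source order within one basic graph pattern.

## Query repair

Pipeline order: missing-prefix injection → named-subquery inlining → hint
stripping. Each output is guaranteed to parse under the strict grammar, and
the pipeline is idempotent.

* **Prefixes** are resolved from a registry of common namespaces with an
  optional project overlay (overlay wins on collision). The scan is
  token-level over masked text — necessarily so, because a missing prefix
  makes the query unparseable. Declarations are prepended in first-use
  order. An unresolvable label is an error naming the label.
* **Named subqueries** use the Blazegraph/Anzo dialect
  (`WITH { <subselect> } AS %name` before WHERE, `INCLUDE %name` in group
  patterns), the form widespread in the Wikidata community. Every INCLUDE is
  replaced in place by the braced subselect; multiple INCLUDEs duplicate it
  (names-apart rewriting was the alternative; duplication keeps the output
  dependency-free). An INCLUDE of an undefined name is an error; a never
  included WITH block is dropped with a warning.
* **Hint triples** — statements whose subject or predicate IRI falls in a
  configured hint namespace (defaults: Blazegraph `queryHints#`, AWS Neptune
  query hints) — are removed whole. They carry engine directives, match no
  data elsewhere, and would make migrated queries return empty results. If
  stripping empties a WHERE pattern the query was all hints, which is an
  error rather than a silent no-op. Comments outside rewritten spans are
  preserved verbatim.

## Publishing

Merged per-endpoint graphs use the named-graph IRI
`<endpoint>` + `/.well-known/sparql-examples` (the slash is inserted only
when the endpoint IRI does not end with one). Shared prefix declarations are
materialized into each example so the merged Turtle file is self-contained.
The keyword search runs the standard "querying for queries" SELECT with a
case-sensitive `contains` on the question literal (a case-insensitive flag
is provided); results are deduplicated to one row per example so that a
bilingual example is not reported twice. The Bio-Query JSON schema is this
package's own: `id`, `category` (resource folder), `label` (first English
question, else first question), `query`, `endpoints`, `keywords`, ordered by
identifier.

## VoID and autocomplete

VoID descriptions are computed by exhaustive counting: class partitions
count distinct typed subjects, property partitions count triples per
predicate (their sum equals the triple total — a conservation invariant
under test), and linkage rows count (subject class, property, object class)
co-occurrences. The object's "class" is its rdf:type if typed, its literal
datatype if a literal (`rdf:langString` / `xsd:string` when untyped), else
an unknown-class marker; subjects with several types contribute one row per
type, so linkage rows may overlap across classes while the per-property
conservation stays global. Standard VoID has no linkage vocabulary, so rows
are emitted as nested property partitions under the subject's class
partition with a `void-ext:objectClassPartition` object marker — a
documented convention, readable back by this package.

Autocomplete restricts predicate suggestions to properties the linkage
actually states for the focused class — this is what makes the suggestions
*precise* rather than schema-wide — falling back, flagged unscoped, to all
property partitions when the class is unknown. Ranking is by descending
occurrence count, ties broken by IRI, so identical inputs give identical
lists.

The compliance checker verifies the two metadata requirements offline on a
dump: the examples named graph exists and holds at least one well-formed
example (validated with the standard rules; malformed ones are flagged), and
a VoID description with at least one class partition is present. Each
failure yields a concrete remediation step.

## Synthetic fixtures

The generator emulates a small but representative collection: three resource
folders with their own endpoints, multilingual questions (English always,
German ~30 % of the time), shared per-folder prefix files, one to eight
triple patterns per query drawn from a fixed join chain over a toy
protein/taxon vocabulary, optional sequence paths, OPTIONAL/UNION/FILTER
decorations, COUNT aggregates, about a quarter of examples with a second
target endpoint, and a federated fraction of 0.1 (federated examples get a
SERVICE clause and a `spex:federatesWith` declaration). The toy dataset
instantiates every hop of the chain, so each clean non-federated query
returns at least one row — which is what makes probe tests meaningful.
Defaults are fixed study conditions, not tuning knobs.

Files are templated directly as Turtle text (not round-tripped through a
serializer), so identical spec and seed give byte-identical trees. Defect
injection mutates otherwise-valid files — each injected code produces
exactly one error-level finding — and records ground truth in a JSON
manifest (per-file identifier, kind, targets, constructional TP count,
federation flag, defects, question text), against which detection
completeness is tested.

What the fixtures do **not** emulate: real KG schemas and their skew, very
large queries, non-UTF-8 encodings, HTTP content-negotiation quirks of live
endpoints. Passing tests demonstrate correctness of the machinery, not
robustness to every artifact of a decade-old hand-curated collection.

## Problem sizes

The shipped verification uses: 500 grammar-sampled queries for the
TP-count/oracle comparison, 20 seeded collections of 15 examples (one
injected defect of each of nine classes) plus 20 clean collections for
detection completeness and false positives, 200 queries for
visualization/analysis agreement and render determinism, 100 random graphs
for VoID conservation and suggestion soundness, 100 queries for fixer
idempotence, and one 50-example collection for the end-to-end
load–validate–probe–merge–search pipeline.

## Known limitations

* The "dual parser" of the syntax check is one parser library run in two
  stages, not two independent codebases; grammar corner cases rdflib accepts
  leniently are accepted here.
* The hint stripper's statement scanner assumes hint triples are standalone
  statements (their universal form in practice); a hint IRI buried in a
  predicate-object list with `;` continuation on a non-hint subject is out of
  scope.
* Property-path decomposition inside nested path expressions follows the
  stated convention; other tools may count `p1/p2` as one pattern, so
  cross-tool TP statistics are comparable only under the same convention.
* Remote probing and live-endpoint compliance checks exist behind the
  network opt-in but are exercised only against local graphs in the test
  suite.
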