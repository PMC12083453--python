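# sparql-examples-kit

Tooling for collections of **natural-language question / SPARQL query
examples** over bioinformatics knowledge graphs.

Life-science RDF resources (UniProt, Bgee, OMA, Rhea, …) publish curated
example queries so users — and, increasingly, question-answering systems —
can learn how to interrogate their SPARQL endpoints. This package implements
a standardized, machine-readable representation for such examples and the
maintenance tooling built on top of it: validation, execution probes,
complexity statistics, query-graph visualization, automatic repair of
vendor-specific SPARQL, per-endpoint publishing, VoID-driven autocomplete and
endpoint metadata compliance checking.

## The representation

One example per Turtle file, in a folder named after the contributing
resource. The example is a SHACL `SPARQLExecutable` (with the form-specific
subtype, e.g. `sh:SPARQLSelectExecutable`); the question is an
`rdfs:comment` with a language tag; the query hangs off `sh:select` /
`sh:ask` / `sh:construct` / `sh:update`, or `spex:describe` for DESCRIBE
queries (which SHACL cannot express — such documents are typed
`sh:SPARQLExecutable` only); endpoints are `schema:target`, tags are
`schema:keywords`, and `spex:federatesWith` declares the remote endpoints a
federated query joins via `SERVICE`:

```turtle
PREFIX ex: <https://sparql.uniprot.org/.well-known/sparql-examples/>
PREFIX sh: <http://www.w3.org/ns/shacl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX schema: <https://schema.org/>

ex:001 a sh:SPARQLSelectExecutable, sh:SPARQLExecutable ;
    rdfs:comment "Select all taxa from the UniProt taxonomy"@en ;
    sh:select """PREFIX up: <http://purl.uniprot.org/core/>
SELECT ?taxon
FROM <http://sparql.uniprot.org/taxonomy>
WHERE {
    ?taxon a up:Taxon .
}""" ;
    schema:target <https://sparql.uniprot.org/sparql/> ;
    schema:keywords "taxa." .
```

Collections are published per endpoint into the named graph
`<endpoint>/.well-known/sparql-examples`, after which plain SPARQL finds
them ("querying for queries"):

```sparql
SELECT * WHERE {
    ?ex sh:select ?query .
    ?ex rdfs:comment ?question .
    FILTER (contains(?question, "species"))
}
```

## Worked example

```python
from sparql_examples import parse_example
from sparql_examples.example_model import canonical_example_text
from sparql_examples.query_analysis import analyze_query
from sparql_examples.validation import validate_example
from sparql_examples.visualization import build_query_graph, render_mermaid

ex = parse_example(canonical_example_text())
print(ex.kind.value, ex.question())
print(validate_example(ex).passed)
print(analyze_query(ex.query_text).triple_pattern_count)
print(render_mermaid(build_query_graph(ex.query_text, ex.prefixes)).text)
```

prints

```
select Select all taxa from the UniProt taxonomy
True
1
graph TD
  v_taxon["?taxon"]
  i_up_x3aTaxon(["up:Taxon"])
  v_taxon -- "1. a" --> i_up_x3aTaxon
  classDef projected fill:#c6e48b,stroke:#2e7d32;
  classDef anonymous fill:#eeeeee,stroke:#999999;
  class v_taxon projected;
```

— the query has one triple pattern (one join hop), and the Mermaid diagram
shows the projected variable `?taxon` (styled green) reaching `up:Taxon`
through an `a` (`rdf:type`) edge, numbered to match the pattern in the query.

## Command line

```sh
sparql-examples validate <folder>         # metadata + syntax rules, exit 1 on findings
sparql-examples probe <folder> --dataset toy.ttl   # LIMIT-1 execution probes
sparql-examples stats <folder>            # per-endpoint TP/aggregation table
sparql-examples viz <folder> --out pages/ # Markdown + Mermaid pages
sparql-examples fix query.rq              # prefixes, named subqueries, hint triples
sparql-examples merge <folder> --endpoint <iri> --out merged.ttl
sparql-examples void dataset.ttl --iri <dataset-iri>
sparql-examples check dump.trig --endpoint <iri>
sparql-examples fixtures --out demo/ --seed 1      # synthetic collection
```

No command touches the network unless `--network` is passed.

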