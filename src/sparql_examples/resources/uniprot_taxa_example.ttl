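# The canonical "all taxa" example published by the UniProt SPARQL endpoint,
# in the standard question-query representation.  Used as the worked example
# throughout the documentation and tests.
PREFIX ex: <https://sparql.uniprot.org/.well-known/sparql-examples/>
PREFIX sh: <http://www.w3.org/ns/shacl#>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX schema: <https://schema.org/>

ex:001 a sh:SPARQLSelectExecutable, sh:SPARQLExecutable ;
    sh:prefixes _:sparql_examples_prefixes ;
    rdfs:comment "Select all taxa from the UniProt taxonomy"@en ;
    sh:select """PREFIX up: <http://purl.uniprot.org/core/>
SELECT ?taxon
FROM <http://sparql.uniprot.org/taxonomy>
WHERE {
    ?taxon a up:Taxon .
}""" ;
    schema:target <https://sparql.uniprot.org/sparql/> ;
    schema:keywords "taxa." .

_:sparql_examples_prefixes sh:declare [
    sh:prefix "up" ;
    sh:namespace "http://purl.uniprot.org/core/"^^<http://www.w3.org/2001/XMLSchema#anyURI> ;
] .
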