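# SHACL shapes expressing the metadata rules for example documents.
# The validation module evaluates the same rules natively; this document is
# shipped so external SHACL engines can run them over a merged collection.
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix schema: <https://schema.org/> .
@prefix spex: <https://purl.expasy.org/sparql-examples/ontology#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
@prefix ex: <https://purl.expasy.org/sparql-examples/shapes#> .

ex:ExampleShape
    a sh:NodeShape ;
    sh:targetClass sh:SPARQLExecutable ;
    rdfs:comment "Mandatory metadata for a question-query example: IRI identifier, at least one question with a language tag, at least one target endpoint, exactly one query property." ;
    sh:nodeKind sh:IRI ;
    sh:property [
        sh:path rdfs:comment ;
        sh:minCount 1 ;
        sh:message "an example needs at least one rdfs:comment question" ;
    ] ;
    sh:property [
        sh:path rdfs:comment ;
        sh:qualifiedValueShape [ sh:datatype rdf:langString ] ;
        sh:qualifiedMinCount 1 ;
        sh:message "at least one question must carry a language tag" ;
    ] ;
    sh:property [
        sh:path schema:target ;
        sh:minCount 1 ;
        sh:nodeKind sh:IRI ;
        sh:message "an example needs at least one schema:target endpoint" ;
    ] .

ex:SelectShape
    a sh:NodeShape ;
    sh:targetClass sh:SPARQLSelectExecutable ;
    sh:property [
        sh:path sh:select ;
        sh:minCount 1 ;
        sh:maxCount 1 ;
        sh:message "a SELECT example carries exactly one sh:select query" ;
    ] .

ex:AskShape
    a sh:NodeShape ;
    sh:targetClass sh:SPARQLAskExecutable ;
    sh:property [
        sh:path sh:ask ;
        sh:minCount 1 ;
        sh:maxCount 1 ;
        sh:message "an ASK example carries exactly one sh:ask query" ;
    ] .

# DESCRIBE examples are typed sh:SPARQLExecutable only and use spex:describe.
ex:DescribeShape
    a sh:NodeShape ;
    sh:targetSubjectsOf spex:describe ;
    sh:property [
        sh:path spex:describe ;
        sh:maxCount 1 ;
    ] .
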