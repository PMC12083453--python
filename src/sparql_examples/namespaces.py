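"""Vocabulary IRIs used by the example representation."""

from rdflib import Namespace
from rdflib.namespace import RDF, RDFS, XSD  # noqa: F401  (re-exported)

SH = Namespace("http://www.w3.org/ns/shacl#")
#: Extension vocabulary for concepts SHACL lacks (DESCRIBE queries, federation).
SPEX = Namespace("https://purl.expasy.org/sparql-examples/ontology#")
SCHEMA = Namespace("https://schema.org/")
#: Legacy http:// form of schema.org, accepted on input.
SCHEMA_HTTP = Namespace("http://schema.org/")
VOID = Namespace("http://rdfs.org/ns/void#")
#: Extension terms for class/property linkage partitions in VoID output.
VOID_EXT = Namespace("http://ldf.fi/void-ext#")

#: Namespace bindings used when serializing example documents.
EXAMPLE_BINDINGS = {
    "sh": SH,
    "spex": SPEX,
    "schema": SCHEMA,
    "rdf": RDF,
    "rdfs": RDFS,
    "xsd": XSD,
}
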