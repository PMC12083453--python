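"""Data model and Turtle round-trip behavior."""

from __future__ import annotations

import pytest
from rdflib.compare import isomorphic

from sparql_examples.errors import (
    CollectionError,
    ExampleParseError,
    ExampleStructureError,
    MissingQueryError,
    SerializationError,
)
from sparql_examples.example_model import (
    ExampleDocument,
    PrefixMap,
    QueryKind,
    load_collection,
    parse_example,
    serialize_example,
)
from sparql_examples.fixtures import FixtureSpec, generate_fixture_collection


class TestPrefixMap:
    def test_valid_entries_and_curie(self):
        pm = PrefixMap({"up": "http://purl.uniprot.org/core/", "": "http://example.org/"})
        assert pm.get("up") == "http://purl.uniprot.org/core/"
        assert pm.curie("http://purl.uniprot.org/core/Taxon") == "up:Taxon"
        assert pm.curie("http://other.org/x") is None

    @pytest.mark.parametrize("label", ["1bad", "-bad", "with space", "end.", ".start"])
    def test_bad_labels_rejected(self, label):
        with pytest.raises(ValueError):
            PrefixMap({label: "http://example.org/"})

    def test_relative_namespace_rejected(self):
        with pytest.raises(ValueError):
            PrefixMap({"x": "not-an-iri"})

    def test_longest_namespace_wins(self):
        pm = PrefixMap({"a": "http://e.org/", "b": "http://e.org/deep/"})
        assert pm.curie("http://e.org/deep/x") == "b:x"


class TestKindPropertyBijection:
    def test_bijection(self):
        seen_properties = set()
        for kind in QueryKind:
            prop = kind.query_property
            assert QueryKind.from_property(prop) is kind
            seen_properties.add(prop)
        assert len(seen_properties) == len(QueryKind)

    def test_describe_has_no_subtype(self):
        assert QueryKind.DESCRIBE.shacl_subtype is None
        assert QueryKind.SELECT.shacl_subtype is not None


class TestParseCanonical:
    def test_fields(self, canonical_example):
        ex = canonical_example
        assert ex.kind is QueryKind.SELECT
        assert ex.identifier == "https://sparql.uniprot.org/.well-known/sparql-examples/001"
        assert ex.comments == [("Select all taxa from the UniProt taxonomy", "en")]
        assert ex.targets == ["https://sparql.uniprot.org/sparql/"]
        assert ex.keywords == ["taxa."]  # preserved verbatim, trailing dot included
        assert "?taxon a up:Taxon" in ex.query_text
        assert ex.prefixes.get("up") == "http://purl.uniprot.org/core/"

    def test_roundtrip_isomorphic(self, canonical_example):
        text = serialize_example(canonical_example)
        again = parse_example(text)
        assert isomorphic(canonical_example.to_graph(), again.to_graph())


MINIMAL_DESCRIBE = """\
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix schema: <https://schema.org/> .
@prefix spex: <https://purl.expasy.org/sparql-examples/ontology#> .
<http://example.org/ex/1> a sh:SPARQLExecutable ;
    rdfs:comment "Describe the example entity"@en ;
    spex:describe "DESCRIBE <http://example.org/x>" ;
    schema:target <http://example.org/sparql> .
"""

MINIMAL_ASK = """\
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix schema: <https://schema.org/> .
<http://example.org/ex/2> a sh:SPARQLAskExecutable, sh:SPARQLExecutable ;
    rdfs:comment "Is there any triple?"@en ;
    sh:ask "ASK { ?s ?p ?o }" ;
    schema:target <http://example.org/sparql> .
"""


class TestParseKinds:
    def test_describe_document(self):
        ex = parse_example(MINIMAL_DESCRIBE)
        assert ex.kind is QueryKind.DESCRIBE

    def test_ask_document(self):
        ex = parse_example(MINIMAL_ASK)
        assert ex.kind is QueryKind.ASK

    def test_describe_serializes_single_type(self):
        ex = parse_example(MINIMAL_DESCRIBE)
        text = serialize_example(ex)
        assert "spex:describe" in text or "describe" in text
        graph = parse_example(text).to_graph()
        from rdflib.namespace import RDF

        subject = next(graph.subjects(RDF.type, None))
        assert len(list(graph.objects(subject, RDF.type))) == 1


class TestParseErrors:
    def test_malformed_turtle_reports_line(self):
        with pytest.raises(ExampleParseError):
            parse_example("@prefix sh: <oops .")

    def test_no_example_subject(self):
        with pytest.raises(ExampleStructureError):
            parse_example("<http://a> <http://b> <http://c> .")

    def test_missing_query_property(self):
        text = """@prefix sh: <http://www.w3.org/ns/shacl#> .
<http://example.org/e> a sh:SPARQLExecutable ."""
        with pytest.raises(MissingQueryError):
            parse_example(text)

    def test_two_subjects_rejected(self):
        text = MINIMAL_ASK + MINIMAL_DESCRIBE.replace("@prefix", "#")  # merge would be invalid
        two = (
            MINIMAL_ASK
            + "\n<http://example.org/ex/3> sh:ask \"ASK { ?s ?p ?o }\" .\n"
        )
        with pytest.raises(ExampleStructureError):
            parse_example(two)

    def test_multiple_query_properties_rejected(self):
        text = MINIMAL_ASK.replace(
            'sh:ask "ASK { ?s ?p ?o }" ;',
            'sh:ask "ASK { ?s ?p ?o }" ; sh:select "SELECT * WHERE { ?s ?p ?o }" ;',
        )
        with pytest.raises(ExampleStructureError):
            parse_example(text)


class TestSerializationRefusal:
    @pytest.mark.parametrize(
        "mutation, named",
        [
            (dict(identifier=None), "identifier"),
            (dict(comments=[]), "comments"),
            (dict(targets=[]), "targets"),
            (dict(query_text="  "), "query_text"),
            (dict(comments=[("no tag", None)]), "language tag"),
        ],
    )
    def test_violations_are_named(self, mutation, named):
        base = dict(
            identifier="http://example.org/e",
            kind=QueryKind.SELECT,
            query_text="SELECT * WHERE { ?s ?p ?o }",
            comments=[("q", "en")],
            targets=["http://example.org/sparql"],
        )
        base.update(mutation)
        with pytest.raises(SerializationError, match=named.split()[0]):
            serialize_example(ExampleDocument(**base))

    def test_two_language_comments_preserved(self):
        ex = ExampleDocument(
            identifier="http://example.org/e",
            kind=QueryKind.SELECT,
            query_text="SELECT * WHERE { ?s ?p ?o }",
            comments=[("question", "en"), ("Frage", "de")],
            targets=["http://example.org/sparql"],
        )
        again = parse_example(serialize_example(ex))
        assert sorted(again.comments) == [("Frage", "de"), ("question", "en")]


class TestLoadCollection:
    def test_counts_and_resource_of(self, tmp_path):
        spec = FixtureSpec(
            n_examples=5,
            resources=("bgee", "uniprot"),
            endpoints=("https://www.bgee.org/sparql/", "https://sparql.uniprot.org/sparql/"),
            seed=4,
        )
        manifest = generate_fixture_collection(spec, tmp_path)
        collection = load_collection(tmp_path)
        assert len(collection) == 5
        per_resource = {r: len(v) for r, v in collection.by_resource().items()}
        assert per_resource == {"bgee": 3, "uniprot": 2}
        for entry in manifest["files"].values():
            assert collection.resource_of[entry["identifier"]] == entry["resource"]

    def test_empty_folder(self, tmp_path):
        assert len(load_collection(tmp_path)) == 0

    def test_duplicate_identifiers_error_names_both_files(self, tmp_path):
        (tmp_path / "res").mkdir()
        doc = MINIMAL_ASK
        (tmp_path / "res" / "a.ttl").write_text(doc, encoding="utf-8")
        (tmp_path / "res" / "b.ttl").write_text(doc, encoding="utf-8")
        with pytest.raises(CollectionError) as excinfo:
            load_collection(tmp_path)
        assert "a.ttl" in str(excinfo.value) and "b.ttl" in str(excinfo.value)
        lenient = load_collection(tmp_path, strict_duplicates=False)
        assert len(lenient.duplicates) == 1

    def test_load_failures_recorded_not_raised(self, tmp_path):
        (tmp_path / "res").mkdir()
        (tmp_path / "res" / "bad.ttl").write_text("@prefix broken", encoding="utf-8")
        (tmp_path / "res" / "good.ttl").write_text(MINIMAL_ASK, encoding="utf-8")
        collection = load_collection(tmp_path)
        assert len(collection) == 1
        assert len(collection.load_failures) == 1

    def test_order_independent(self, tmp_path):
        spec = FixtureSpec(n_examples=8, seed=9)
        generate_fixture_collection(spec, tmp_path)
        first = load_collection(tmp_path)
        second = load_collection(tmp_path)
        assert [e.identifier for e in first.examples] == [e.identifier for e in second.examples]
        assert first.resource_of == second.resource_of

    def test_shared_prefixes_attached_from_folder_file(self, tmp_path):
        generate_fixture_collection(FixtureSpec(n_examples=8, seed=2), tmp_path)
        collection = load_collection(tmp_path)
        assert all(example.prefixes.get("voc") for example in collection.examples)
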