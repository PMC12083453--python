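"""VoID generation, autocomplete suggestions and compliance checking."""

from __future__ import annotations

import random

import pytest
from rdflib import Dataset, Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

from sparql_examples.example_model import parse_example
from sparql_examples.fixtures import generate_toy_dataset
from sparql_examples.publishing import named_graph_iri
from sparql_examples.void_autocomplete import (
    UNKNOWN_CLASS,
    check_metadata_compliance,
    generate_void,
    suggest_completions,
    void_from_graph,
)

from .oracles import oracle_void_counts

X = Namespace("http://ex.org/")


@pytest.fixture()
def taxon_graph() -> Graph:
    """Three subjects typed :Taxon, each with one rdfs:label (6 triples)."""
    g = Graph()
    for i in range(3):
        subject = X[f"t{i}"]
        g.add((subject, RDF.type, X.Taxon))
        g.add((subject, RDFS.label, Literal(f"taxon {i}")))
    return g


def random_graph(seed: int) -> Graph:
    rng = random.Random(seed)
    g = Graph()
    classes = [X.A, X.B, X.C]
    predicates = [X.p, X.q, RDFS.label]
    for i in range(rng.randint(0, 40)):
        subject = X[f"s{rng.randint(0, 9)}"]
        if rng.random() < 0.5:
            g.add((subject, RDF.type, rng.choice(classes)))
        predicate = rng.choice(predicates)
        if rng.random() < 0.4:
            g.add((subject, predicate, Literal(f"v{i}")))
        else:
            g.add((subject, predicate, X[f"o{rng.randint(0, 9)}"]))
    return g


class TestGenerateVoid:
    def test_taxon_toy_graph_counts(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        assert void.total_triples == 6
        assert void.class_partitions == [(str(X.Taxon), 3)]
        assert (str(RDF.type), 3) in void.property_partitions
        assert (str(RDFS.label), 3) in void.property_partitions

    def test_empty_dataset(self):
        void = generate_void(Graph(), "http://ex.org/dataset")
        assert void.total_triples == 0
        assert void.class_partitions == [] and void.property_partitions == []

    def test_untyped_subject_gets_unknown_marker(self):
        g = Graph()
        g.add((X.s, X.p, Literal("v")))
        g.add((X.s, X.q, X.o))
        void = generate_void(g, "http://ex.org/dataset")
        assert len(void.property_partitions) == 2
        assert all(row[0] == UNKNOWN_CLASS for row in void.linkage)

    def test_conservation_on_random_graphs(self):
        for seed in range(30):
            g = random_graph(seed)
            void = generate_void(g, "http://ex.org/dataset")
            total, per_predicate = oracle_void_counts(g)
            assert void.total_triples == total
            assert dict(void.property_partitions) == per_predicate
            assert sum(n for _, n in void.property_partitions) == total

    def test_linkage_counts_bounded_by_property_partition(self):
        for seed in range(10):
            void = generate_void(random_graph(seed), "http://ex.org/dataset")
            partition = dict(void.property_partitions)
            for _s, prop, _o, count in void.linkage:
                assert count <= partition[prop]

    def test_serialization_roundtrip(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        back = void_from_graph(void.to_graph())
        assert back.total_triples == void.total_triples
        assert back.class_partitions == void.class_partitions
        # read-back property partitions include linkage rows for untracked
        # subject classes; the standard partitions must all be present
        assert set(void.property_partitions) <= set(back.property_partitions)


class TestSuggestions:
    def test_scoped_predicate_suggestions(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        suggestions = suggest_completions(void, "predicate", focus_class=str(X.Taxon))
        assert {s.iri for s in suggestions} == {str(RDF.type), str(RDFS.label)}
        assert all(s.scoped for s in suggestions)

    def test_partial_filters_by_prefix(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        suggestions = suggest_completions(
            void, "predicate", focus_class=str(X.Taxon), partial="lab"
        )
        assert [s.iri for s in suggestions] == [str(RDFS.label)]

    def test_unknown_focus_class_falls_back_unscoped(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        suggestions = suggest_completions(
            void, "predicate", focus_class="http://ex.org/Nothing"
        )
        assert suggestions and not any(s.scoped for s in suggestions)

    def test_class_position_lists_class_partitions(self, taxon_graph):
        void = generate_void(taxon_graph, "http://ex.org/dataset")
        suggestions = suggest_completions(void, "class")
        assert [s.iri for s in suggestions] == [str(X.Taxon)]

    def test_ranking_deterministic_and_by_count(self):
        g = Graph()
        for i in range(5):
            g.add((X[f"s{i}"], RDF.type, X.A))
            g.add((X[f"s{i}"], X.common, Literal(i)))
        g.add((X.s0, X.rare, Literal("x")))
        void = generate_void(g, "http://ex.org/dataset")
        first = suggest_completions(void, "predicate", focus_class=str(X.A))
        second = suggest_completions(void, "predicate", focus_class=str(X.A))
        assert [s.iri for s in first] == [s.iri for s in second]
        counts = [s.count for s in first]
        assert counts == sorted(counts, reverse=True)

    def test_suggestion_soundness(self):
        for seed in range(15):
            g = random_graph(seed)
            void = generate_void(g, "http://ex.org/dataset")
            for class_iri, _ in void.class_partitions:
                for s in suggest_completions(void, "predicate", focus_class=class_iri):
                    stated = any(
                        (subj, URIRef(s.iri), None) in g
                        for subj in g.subjects(RDF.type, URIRef(class_iri))
                    )
                    assert stated, (class_iri, s.iri)


def _compliance_dataset(merged_graph, include_void: bool, endpoint: str) -> Dataset:
    ds = Dataset()
    target = ds.graph(URIRef(named_graph_iri(endpoint)))
    for triple in merged_graph:
        target.add(triple)
    if include_void:
        void_graph = ds.graph(URIRef("http://ex.org/void-graph"))
        description = generate_void(generate_toy_dataset(2, 2), "http://ex.org/dataset")
        for triple in description.to_graph():
            void_graph.add(triple)
    return ds


class TestCompliance:
    ENDPOINT = "https://sparql.uniprot.org/sparql/"

    def test_fully_compliant_dump(self, canonical_text):
        example = parse_example(canonical_text)
        ds = _compliance_dataset(example.to_graph(), True, self.ENDPOINT)
        report = check_metadata_compliance(ds, self.ENDPOINT)
        assert report.compliant
        assert report.has_examples_graph and report.has_void
        assert report.example_count == 1
        assert report.suggestions == []

    def test_missing_void_yields_void_suggestion(self, canonical_text):
        example = parse_example(canonical_text)
        ds = _compliance_dataset(example.to_graph(), False, self.ENDPOINT)
        report = check_metadata_compliance(ds, self.ENDPOINT)
        assert not report.compliant
        assert any("VoID" in s for s in report.suggestions)

    def test_missing_examples_graph(self):
        ds = _compliance_dataset(Graph(), True, self.ENDPOINT)
        report = check_metadata_compliance(ds, self.ENDPOINT)
        assert not report.has_examples_graph
        assert any("named graph" in s for s in report.suggestions)

    def test_invalid_example_not_counted_but_flagged(self, canonical_text):
        valid = parse_example(canonical_text)
        combined = valid.to_graph()
        # second example with no comment and no target: well-known defects
        from sparql_examples.namespaces import SH

        broken = URIRef("http://ex.org/broken")
        combined.add((broken, RDF.type, SH.SPARQLSelectExecutable))
        combined.add((broken, SH.select, Literal("SELECT * WHERE { ?s ?p ?o }")))
        ds = _compliance_dataset(combined, True, self.ENDPOINT)
        report = check_metadata_compliance(ds, self.ENDPOINT)
        assert report.example_count == 1
        assert any("malformed" in s for s in report.suggestions)
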