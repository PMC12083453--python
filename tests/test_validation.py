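"""Metadata/syntax rules, probe rewriting and execution probes."""

from __future__ import annotations

import dataclasses

import pytest

from sparql_examples._sparql import set_result_limit, strict_parse
from sparql_examples.errors import UpdateQueryRefused
from sparql_examples.example_model import ExampleDocument, QueryKind, load_collection
from sparql_examples.fixtures import FixtureSpec, generate_fixture_collection
from sparql_examples.validation import (
    Severity,
    probe_example,
    shapes_graph,
    validate_collection,
    validate_example,
)


def make_example(**overrides) -> ExampleDocument:
    base = dict(
        identifier="http://example.org/ex/1",
        kind=QueryKind.SELECT,
        query_text=(
            "PREFIX voc: <http://example.org/voc#>\n"
            "SELECT ?t WHERE { ?t a voc:Taxon . }"
        ),
        comments=[("All taxa", "en")],
        targets=["http://example.org/sparql"],
    )
    base.update(overrides)
    return ExampleDocument(**base)


class TestRules:
    def test_canonical_passes(self, canonical_example):
        report = validate_example(canonical_example)
        assert report.passed and not report.issues

    def test_missing_comment(self, canonical_example):
        broken = dataclasses.replace(canonical_example, comments=[])
        assert "MISSING_COMMENT" in validate_example(broken).codes()

    def test_missing_target(self):
        assert "MISSING_TARGET" in validate_example(make_example(targets=[])).codes()

    def test_missing_language_tag(self):
        ex = make_example(comments=[("untagged", None)])
        assert "MISSING_LANGUAGE_TAG" in validate_example(ex).codes()

    def test_missing_id(self):
        assert "MISSING_ID" in validate_example(make_example(identifier=None)).codes()

    def test_missing_type(self):
        ex = make_example(declared_types=[])
        assert "MISSING_TYPE" in validate_example(ex).codes()

    def test_syntax_error(self):
        ex = make_example(query_text="SELECT ?t WHERE { ?t a ")
        report = validate_example(ex)
        assert "SYNTAX_ERROR" in report.codes() and not report.passed

    def test_type_query_mismatch_on_declared_type(self):
        ex = make_example(
            declared_types=[
                "http://www.w3.org/ns/shacl#SPARQLAskExecutable",
                "http://www.w3.org/ns/shacl#SPARQLExecutable",
            ]
        )
        assert "TYPE_QUERY_MISMATCH" in validate_example(ex).codes()

    def test_type_query_mismatch_on_parsed_form(self):
        ex = make_example(query_text="ASK { ?s ?p ?o }")
        assert "TYPE_QUERY_MISMATCH" in validate_example(ex).codes()

    def test_federated_without_service(self):
        ex = make_example(federates_with=["https://query.wikidata.org/sparql"])
        report = validate_example(ex)
        assert "FEDERATED_WITHOUT_SERVICE" in report.codes()
        assert not report.passed

    def test_undeclared_federation_is_warning(self):
        ex = make_example(
            query_text=(
                "SELECT ?s WHERE { SERVICE <https://query.wikidata.org/sparql> "
                "{ ?s ?p ?o } }"
            )
        )
        report = validate_example(ex)
        issue = next(i for i in report.issues if i.code == "UNDECLARED_FEDERATION")
        assert issue.severity is Severity.WARNING
        assert report.passed  # warnings do not fail validation

    def test_service_in_literal_not_flagged(self):
        # the SERVICE check works on the algebra, not the raw text
        ex = make_example(
            query_text='SELECT ?s WHERE { ?s ?p ?o . FILTER (?o = "SERVICE <x> {}") }'
        )
        assert "UNDECLARED_FEDERATION" not in validate_example(ex).codes()

    def test_declared_federation_via_keyword(self):
        ex = make_example(keywords=["federated"])
        assert "FEDERATED_WITHOUT_SERVICE" in validate_example(ex).codes()

    def test_purity(self):
        ex = make_example(federates_with=["https://query.wikidata.org/sparql"])
        first, second = validate_example(ex), validate_example(ex)
        assert [i.to_dict() for i in first.issues] == [i.to_dict() for i in second.issues]


class TestCollectionValidation:
    def test_clean_collection_passes(self, clean_collection):
        collection, _ = clean_collection
        report = validate_collection(collection)
        assert report.passed
        assert report.examples_checked == len(collection)

    def test_empty_collection_vacuous_pass(self, tmp_path):
        report = validate_collection(load_collection(tmp_path))
        assert report.passed and report.examples_checked == 0

    def test_each_injected_defect_reported_once(self, defect_collection):
        collection, manifest = defect_collection
        report = validate_collection(collection)
        got = sorted(issue.code for issue in report.errors())
        expected = sorted(
            code for code, files in manifest["defect_files"].items() for _ in files
        )
        assert got == expected

    def test_seven_defect_classes_give_seven_errors(self, tmp_path):
        defects = {
            code: 1
            for code in (
                "SYNTAX_ERROR",
                "MISSING_TYPE",
                "MISSING_COMMENT",
                "MISSING_TARGET",
                "MISSING_LANGUAGE_TAG",
                "TYPE_QUERY_MISMATCH",
                "FEDERATED_WITHOUT_SERVICE",
            )
        }
        manifest = generate_fixture_collection(
            FixtureSpec(n_examples=14, seed=23, defects=defects), tmp_path
        )
        report = validate_collection(load_collection(tmp_path, strict_duplicates=False))
        errors = report.errors()
        assert len(errors) == 7
        assert {issue.code for issue in errors} == set(defects)


class TestLimitRewrite:
    def test_appends_limit_1(self):
        rewrite = set_result_limit("SELECT ?s WHERE { ?s ?p ?o }")
        assert rewrite.query_text.endswith("LIMIT 1")
        strict_parse(rewrite.query_text)

    def test_overrides_larger_limit(self):
        rewrite = set_result_limit("SELECT ?s WHERE { ?s ?p ?o } LIMIT 500")
        assert rewrite.query_text.endswith("LIMIT 1")
        assert rewrite.previous_limit == 500

    def test_limit_zero_kept_and_reported(self):
        rewrite = set_result_limit("SELECT ?s WHERE { ?s ?p ?o } LIMIT 0")
        assert rewrite.query_text.endswith("LIMIT 0")
        assert rewrite.note is not None

    def test_subquery_limit_untouched(self):
        query = "SELECT ?s WHERE { { SELECT ?s WHERE { ?s ?p ?o } LIMIT 5 } }"
        rewrite = set_result_limit(query)
        assert "LIMIT 5" in rewrite.query_text
        assert rewrite.query_text.endswith("LIMIT 1")

    def test_rewrite_preserves_everything_else(self):
        query = "SELECT ?s WHERE { ?s ?p ?o }\nORDER BY ?s"
        rewrite = set_result_limit(query)
        assert rewrite.query_text.removesuffix("\nLIMIT 1") == query

    def test_limit_in_string_literal_ignored(self):
        query = 'SELECT ?s WHERE { ?s ?p "LIMIT 99" }'
        rewrite = set_result_limit(query)
        assert '"LIMIT 99"' in rewrite.query_text
        assert rewrite.query_text.endswith("LIMIT 1")


class TestProbes:
    def test_canonical_reprefixed_probe_ok(self, canonical_example, toy_graph):
        # the canonical taxa query, pointed at the toy vocabulary, finds taxa
        ex = dataclasses.replace(
            canonical_example,
            query_text=canonical_example.query_text.replace(
                "http://purl.uniprot.org/core/", "http://example.org/voc#"
            ).replace("FROM <http://sparql.uniprot.org/taxonomy>\n", ""),
        )
        result = probe_example(ex, toy_graph)
        assert result.outcome == "ok"
        assert result.rewritten_query.endswith("LIMIT 1")

    def test_absent_predicate_probe_empty(self, toy_graph):
        ex = make_example(
            query_text="SELECT ?s WHERE { ?s <http://example.org/voc#nope> ?o }"
        )
        assert probe_example(ex, toy_graph).outcome == "empty"

    def test_ask_runs_unchanged(self, toy_graph):
        ex = make_example(
            kind=QueryKind.ASK,
            query_text="ASK { ?s a <http://example.org/voc#Taxon> }",
        )
        result = probe_example(ex, toy_graph)
        assert result.outcome == "ok"
        assert "LIMIT" not in result.rewritten_query

    def test_update_refused(self, toy_graph):
        ex = make_example(kind=QueryKind.UPDATE, query_text="DELETE WHERE { ?s ?p ?o }")
        with pytest.raises(UpdateQueryRefused):
            probe_example(ex, toy_graph)

    def test_endpoint_probe_without_network_fails(self):
        ex = make_example()
        result = probe_example(ex, "https://example.org/sparql", network_allowed=False)
        assert result.outcome == "failed"
        assert "network" in result.reason

    def test_federated_query_not_executed_locally(self, toy_graph):
        ex = make_example(
            query_text=(
                "SELECT ?s WHERE { SERVICE <https://query.wikidata.org/sparql> "
                "{ ?s ?p ?o } }"
            ),
            federates_with=["https://query.wikidata.org/sparql"],
        )
        result = probe_example(ex, toy_graph, network_allowed=False)
        assert result.outcome == "failed"
        assert "network" in result.reason


def test_shapes_resource_parses():
    graph = shapes_graph()
    assert len(graph) > 0
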