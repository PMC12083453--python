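"""Shared fixtures: synthetic collections, toy graphs, the canonical example."""

from __future__ import annotations

import random

import pytest
from rdflib import Graph

from sparql_examples.example_model import (
    ExampleCollection,
    canonical_example_text,
    load_collection,
    parse_example,
)
from sparql_examples.fixtures import (
    FixtureSpec,
    INJECTABLE_DEFECTS,
    _generate_query,
    generate_fixture_collection,
    generate_toy_dataset,
)


@pytest.fixture(scope="session")
def canonical_text() -> str:
    return canonical_example_text()


@pytest.fixture()
def canonical_example(canonical_text):
    return parse_example(canonical_text)


@pytest.fixture(scope="session")
def toy_graph() -> Graph:
    return generate_toy_dataset(n_taxa=5, n_proteins=5, seed=0)


@pytest.fixture(scope="session")
def clean_collection(tmp_path_factory) -> tuple[ExampleCollection, dict]:
    folder = tmp_path_factory.mktemp("clean")
    manifest = generate_fixture_collection(FixtureSpec(n_examples=20, seed=11), folder)
    return load_collection(folder), manifest


@pytest.fixture(scope="session")
def defect_collection(tmp_path_factory) -> tuple[ExampleCollection, dict]:
    folder = tmp_path_factory.mktemp("defect")
    spec = FixtureSpec(
        n_examples=20, seed=17, defects={code: 1 for code in INJECTABLE_DEFECTS}
    )
    manifest = generate_fixture_collection(spec, folder)
    return load_collection(folder, strict_duplicates=False), manifest


def grammar_queries(n: int, seed: int) -> list[str]:
    """Sample ``n`` queries from the closed fixture query grammar."""
    rng = random.Random(seed)
    prefixes = (
        "PREFIX voc: <http://example.org/voc#>\n"
        "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
    )
    out = []
    for i in range(n):
        generated = _generate_query(rng, federated=rng.random() < 0.15)
        out.append(prefixes + generated.text)
    return out
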