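"""Deterministic synthetic example collections and a toy RDF dataset.

The generator emulates a real example-collection repository at desk scale:
per-resource folders of Turtle files (SELECT/ASK/DESCRIBE, multilingual
questions, keywords, multiple targets, a federated fraction with SERVICE
clauses and ``spex:federatesWith`` declarations, shared per-folder prefix
declarations), plus a small protein/taxon graph over which every clean,
non-federated query returns at least one result.

Queries are drawn from a closed grammar — a join chain of up to eight triple
patterns over the toy vocabulary, optionally decorated with a sequence
property path, OPTIONAL, UNION, FILTER, a COUNT aggregate or a SERVICE
clause — so independent test oracles can predict each query's triple-pattern
count; the generator records its own constructional count in the manifest.

Defects can be injected into otherwise-valid files; every injected defect is
recorded ``(file, defect code)`` in the manifest so detection tests can
compare the validator's findings against ground truth.  Identical spec and
seed give byte-identical output trees: files are templated by hand rather
than round-tripped through an RDF serializer.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

from sparql_examples.errors import FixtureSpecError

__all__ = [
    "VOC",
    "DATA",
    "INJECTABLE_DEFECTS",
    "FixtureSpec",
    "generate_fixture_collection",
    "generate_toy_dataset",
]

VOC = Namespace("http://example.org/voc#")
DATA = Namespace("http://example.org/data/")
REMOTE_ENDPOINT = "https://query.wikidata.org/sparql"

#: Defect codes the generator can inject (each produces exactly one
#: error-level validation issue on the mutated file).
INJECTABLE_DEFECTS = (
    "SYNTAX_ERROR",
    "MISSING_ID",
    "MISSING_TYPE",
    "MISSING_COMMENT",
    "MISSING_TARGET",
    "MISSING_LANGUAGE_TAG",
    "TYPE_QUERY_MISMATCH",
    "FEDERATED_WITHOUT_SERVICE",
    "DUPLICATE_ID",
)

_DEFAULT_RESOURCES = ("uniprot", "bgee", "oma")
_DEFAULT_ENDPOINTS = (
    "https://sparql.uniprot.org/sparql/",
    "https://www.bgee.org/sparql/",
    "https://sparql.omabrowser.org/sparql/",
)


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic collection.

    Defaults mirror a small but representative slice of a production
    collection: three contributing resources with their own endpoints, a tenth
    of the examples federated, queries of one to eight triple patterns,
    questions mostly in English with occasional German translations.
    """

    n_examples: int = 20
    resources: tuple[str, ...] = _DEFAULT_RESOURCES
    endpoints: tuple[str, ...] = _DEFAULT_ENDPOINTS
    fraction_federated: float = 0.1
    languages: tuple[str, ...] = ("en", "de")
    defects: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_federated <= 1.0:
            raise FixtureSpecError("fraction_federated must be within [0, 1]")
        if len(self.resources) != len(self.endpoints):
            raise FixtureSpecError("resources and endpoints must pair up")
        unknown = set(self.defects) - set(INJECTABLE_DEFECTS)
        if unknown:
            raise FixtureSpecError(f"unknown defect codes: {sorted(unknown)}")
        if any(count < 0 for count in self.defects.values()):
            raise FixtureSpecError("defect counts must be non-negative")
        if sum(self.defects.values()) > self.n_examples:
            raise FixtureSpecError("more defects requested than examples")
        if self.defects.get("DUPLICATE_ID") and self.n_examples < len(self.resources) + 1:
            raise FixtureSpecError("DUPLICATE_ID needs at least two files in one resource")


def _resource_namespace(resource: str) -> str:
    return f"https://sparql.example.org/{resource}/.well-known/sparql-examples/"


# ---------------------------------------------------------------------------
# query grammar

_CHAIN = (
    "?protein a voc:Protein .",
    "?protein voc:organism ?taxon .",
    "?taxon a voc:Taxon .",
    "?taxon rdfs:label ?taxonLabel .",
    "?protein voc:annotation ?annotation .",
    "?annotation voc:disease ?disease .",
    "?disease a voc:Disease .",
    "?disease rdfs:label ?diseaseLabel .",
)

_QUERY_PREFIXES = (
    "PREFIX voc: <http://example.org/voc#>\n"
    "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
)


@dataclass
class _GeneratedQuery:
    text: str  # query text without PREFIX declarations
    tp_count: int
    kind: str  # select | ask | describe
    federated: bool


def _generate_query(rng: random.Random, federated: bool) -> _GeneratedQuery:
    roll = rng.random()
    if not federated and roll < 0.10:
        return _GeneratedQuery(f"DESCRIBE <{DATA}taxon_0>", 0, "describe", False)
    kind = "ask" if roll < 0.25 else "select"

    k = rng.randint(1, len(_CHAIN))
    patterns = list(_CHAIN[:k])
    tp_count = k

    if k >= 6 and rng.random() < 0.5:
        # collapse the annotation hop into a sequence property path (still 2 TPs)
        patterns[4] = "?protein voc:annotation/voc:disease ?disease ."
        del patterns[5]

    if k >= 3 and rng.random() < 0.2:
        branch = (
            "?taxon voc:scientificName ?sci ." if k >= 2 else "?protein rdfs:label ?pLabel ."
        )
        patterns[-1] = "{ " + patterns[-1] + " } UNION { " + branch + " }"
        tp_count += 1
    elif k >= 2 and rng.random() < 0.3:
        patterns[-1] = "OPTIONAL { " + patterns[-1] + " }"

    if federated:
        patterns[-1] = f"SERVICE <{REMOTE_ENDPOINT}> {{ {patterns[-1]} }}"

    if k >= 2 and rng.random() < 0.3:
        patterns.append("FILTER (isIRI(?protein))")

    body = "\n    ".join(patterns)
    if kind == "ask":
        return _GeneratedQuery(f"ASK {{\n    {body}\n}}", tp_count, kind, federated)
    projection = "*"
    if rng.random() < 0.25:
        projection = "(COUNT(?protein) AS ?proteinCount)"
    return _GeneratedQuery(
        f"SELECT {projection} WHERE {{\n    {body}\n}}", tp_count, kind, federated
    )


# ---------------------------------------------------------------------------
# file templating

_FILE_PREAMBLE = """\
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix schema: <https://schema.org/> .
@prefix spex: <https://purl.expasy.org/sparql-examples/ontology#> .

"""

_KIND_PROPERTY = {"select": "sh:select", "ask": "sh:ask", "describe": "spex:describe"}
_KIND_SUBTYPE = {
    "select": "sh:SPARQLSelectExecutable, sh:SPARQLExecutable",
    "ask": "sh:SPARQLAskExecutable, sh:SPARQLExecutable",
    "describe": "sh:SPARQLExecutable",
}


def _render_example_file(
    identifier: str,
    kind: str,
    query: str,
    comments: list[tuple[str, str | None]],
    targets: list[str],
    keywords: list[str],
    federates_with: list[str],
    prefix_node: str,
    defect: str | None,
) -> str:
    subject = "[]" if defect == "MISSING_ID" else f"<{identifier}>"
    subtype = _KIND_SUBTYPE[kind]
    if defect == "TYPE_QUERY_MISMATCH":
        subtype = (
            "sh:SPARQLAskExecutable, sh:SPARQLExecutable"
            if kind != "ask"
            else "sh:SPARQLSelectExecutable, sh:SPARQLExecutable"
        )
    if defect == "SYNTAX_ERROR":
        query = query.rstrip() + "\nWHERE {"  # unbalanced brace: fails any form

    lines = [f"{subject} a {subtype} ;"]
    lines.append(f"    sh:prefixes <{prefix_node}> ;")
    if defect != "MISSING_COMMENT":
        rendered = []
        for text, lang in comments:
            tag = "" if defect == "MISSING_LANGUAGE_TAG" or lang is None else f"@{lang}"
            escaped = text.replace("\\", "\\\\").replace('"', '\\"')
            rendered.append(f'"{escaped}"{tag}')
        lines.append(f"    rdfs:comment {', '.join(rendered)} ;")
    lines.append(f'    {_KIND_PROPERTY[kind]} """{query}""" ;')
    if defect != "MISSING_TARGET":
        lines.append(f"    schema:target {', '.join(f'<{t}>' for t in targets)} ;")
    if keywords:
        rendered = ", ".join(f'"{k}"' for k in keywords)
        lines.append(f"    schema:keywords {rendered} ;")
    for remote in federates_with:
        lines.append(f"    spex:federatesWith <{remote}> ;")
    lines[-1] = lines[-1].rstrip(" ;") + " ."
    if defect == "MISSING_TYPE":
        lines[0] = f"{subject} sh:prefixes <{prefix_node}> ;"
        del lines[1]
    return _FILE_PREAMBLE + "\n".join(lines) + "\n"


_PREFIXES_FILE = """\
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<{node}> sh:declare
    [ sh:prefix "voc" ; sh:namespace "http://example.org/voc#"^^xsd:anyURI ],
    [ sh:prefix "rdfs" ; sh:namespace "http://www.w3.org/2000/01/rdf-schema#"^^xsd:anyURI ] .
"""


# ---------------------------------------------------------------------------
# collection generation


def generate_fixture_collection(spec: FixtureSpec, out_folder: str | Path) -> dict:
    """Write a synthetic collection under ``out_folder`` and return its manifest.

    The manifest maps each written file to its ground truth: identifier,
    resource, kind, targets, constructional triple-pattern count, federation
    flag, injected defects and whether the question mentions "species".
    """
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)

    n = spec.n_examples
    indices = list(range(n))

    # assign at most one defect per file, deterministically
    defect_of: dict[int, str] = {}
    pool = list(indices)
    for code in sorted(spec.defects):
        for _ in range(spec.defects[code]):
            if code == "DUPLICATE_ID":
                candidates = [i for i in pool if i >= len(spec.resources)]
            else:
                candidates = pool
            if not candidates:
                raise FixtureSpecError(f"cannot place defect {code}")
            chosen = rng.choice(sorted(candidates))
            pool.remove(chosen)
            defect_of[chosen] = code
            if code == "DUPLICATE_ID":
                # the duplicated identifier comes from the resource's first
                # file, which must stay intact (keep it defect-free)
                original = chosen % len(spec.resources)
                if original in pool:
                    pool.remove(original)

    n_federated = round(n * spec.fraction_federated)
    federation_candidates = sorted(
        i
        for i in indices
        if defect_of.get(i) not in ("FEDERATED_WITHOUT_SERVICE", "SYNTAX_ERROR")
    )
    federated_set = set(rng.sample(federation_candidates, min(n_federated, len(federation_candidates))))

    manifest_files: dict[str, dict] = {}
    per_resource_counter: dict[str, int] = {}
    identifier_of: dict[int, str] = {}

    for i in indices:
        resource = spec.resources[i % len(spec.resources)]
        endpoint = spec.endpoints[i % len(spec.resources)]
        number = per_resource_counter.get(resource, 0) + 1
        per_resource_counter[resource] = number
        namespace = _resource_namespace(resource)
        identifier = f"{namespace}{number:03d}"
        defect = defect_of.get(i)
        if defect == "DUPLICATE_ID":
            original = i % len(spec.resources)  # first file of the same resource
            identifier = identifier_of[original]
        identifier_of[i] = identifier

        federated = i in federated_set
        generated = _generate_query(rng, federated)

        species = generated.kind == "select" and i % 3 == 0
        if species:
            question = f"Which species are linked to proteins? (example {resource} {number})"
        elif generated.kind == "describe":
            question = f"Describe the first taxon entry. (example {resource} {number})"
        else:
            question = f"Retrieve proteins with their annotations. (example {resource} {number})"
        comments: list[tuple[str, str | None]] = [(question, spec.languages[0])]
        if len(spec.languages) > 1 and rng.random() < 0.3:
            comments.append(
                (f"Frage {number} für {resource}.", spec.languages[1])
            )

        targets = [endpoint]
        if rng.random() < 0.25:
            other = spec.endpoints[(i + 1) % len(spec.endpoints)]
            if other != endpoint:
                targets.append(other)

        keywords = ["taxa."] if "taxon" in generated.text else ["protein"]
        federates_with = []
        if federated:
            keywords.append("federated")
            federates_with.append(REMOTE_ENDPOINT)
        if defect == "FEDERATED_WITHOUT_SERVICE":
            federates_with.append(REMOTE_ENDPOINT)

        include_inline_prefixes = generated.kind != "describe" and i % 4 != 3
        query_text = (
            _QUERY_PREFIXES + generated.text if include_inline_prefixes else generated.text
        )

        prefix_node = f"{namespace}prefixes"
        content = _render_example_file(
            identifier,
            generated.kind,
            query_text,
            comments,
            targets,
            keywords,
            federates_with,
            prefix_node,
            defect,
        )
        folder = out / resource
        folder.mkdir(parents=True, exist_ok=True)
        filename = f"{number:03d}.ttl"
        (folder / filename).write_text(content, encoding="utf-8")

        manifest_files[f"{resource}/{filename}"] = {
            "identifier": identifier,
            "resource": resource,
            "kind": generated.kind,
            "targets": targets,
            "tp_count": generated.tp_count,
            "federated": federated,
            "defects": [defect] if defect else [],
            "contains_species": "species" in question,
            "question": question,
        }

    for resource in spec.resources:
        if (out / resource).is_dir():
            node = f"{_resource_namespace(resource)}prefixes"
            (out / resource / "prefixes.ttl").write_text(
                _PREFIXES_FILE.format(node=node), encoding="utf-8"
            )

    defect_files: dict[str, list[str]] = {}
    for path, entry in manifest_files.items():
        for code in entry["defects"]:
            defect_files.setdefault(code, []).append(path)

    manifest = {
        "seed": spec.seed,
        "n_examples": n,
        "resources": {r: e for r, e in zip(spec.resources, spec.endpoints)},
        "files": manifest_files,
        "defect_files": {code: sorted(paths) for code, paths in sorted(defect_files.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False), encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# toy dataset


def generate_toy_dataset(n_taxa: int = 5, n_proteins: int = 5, seed: int = 0) -> Graph:
    """A small protein/taxon graph every clean fixture query succeeds on.

    Each taxon has a label, a scientific name and a rank; each protein links
    to a taxon (``voc:organism``) and, through an annotation node, to a
    labeled disease — covering every hop of the fixture query chain.
    Deterministic under ``seed`` (reserved; the layout is fully structural).
    """
    del seed  # layout is structural; the parameter is kept for interface stability
    g = Graph()
    g.bind("voc", VOC)
    g.bind("data", DATA)
    g.bind("rdfs", RDFS)
    for i in range(n_taxa):
        taxon = DATA[f"taxon_{i}"]
        g.add((taxon, RDF.type, VOC.Taxon))
        g.add((taxon, RDFS.label, Literal(f"Taxon {i}", lang="en")))
        g.add((taxon, VOC.scientificName, Literal(f"Taxonus exemplaris {i}")))
        g.add((taxon, VOC.rank, VOC.Species))
    for i in range(n_proteins):
        protein = DATA[f"protein_{i}"]
        g.add((protein, RDF.type, VOC.Protein))
        g.add((protein, RDFS.label, Literal(f"Protein {i}", lang="en")))
        if n_taxa > 0:
            g.add((protein, VOC.organism, DATA[f"taxon_{i % n_taxa}"]))
        annotation = DATA[f"annotation_{i}"]
        disease = DATA[f"disease_{i}"]
        g.add((protein, VOC.annotation, annotation))
        g.add((annotation, RDF.type, VOC.Annotation))
        g.add((annotation, VOC.disease, disease))
        g.add((disease, RDF.type, VOC.Disease))
        g.add((disease, RDFS.label, Literal(f"Disease {i}", lang="en")))
    return g
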