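"""Independent brute-force oracles, written separately from the package code.

The triple-pattern oracle walks the translated algebra with an explicit stack
(the implementation uses a recursive generator) and its own path-length
recursion, so agreement between the two is a meaningful cross-check of the
counting convention.
"""

from __future__ import annotations

import pyparsing
from rdflib.paths import InvPath, SequencePath
from rdflib.plugins.sparql.algebra import translateQuery
from rdflib.plugins.sparql.parser import parseQuery
from rdflib.plugins.sparql.parserutils import CompValue


def _oracle_path_len(predicate) -> int:
    if isinstance(predicate, SequencePath):
        return sum(_oracle_path_len(part) for part in predicate.args)
    if isinstance(predicate, InvPath):
        return _oracle_path_len(predicate.arg)
    return 1


def oracle_tp_count(query_text: str) -> int:
    """Brute-force triple-pattern count over the parsed algebra."""
    algebra = translateQuery(parseQuery(query_text)).algebra
    total = 0
    stack = [algebra]
    while stack:
        node = stack.pop()
        if isinstance(node, CompValue):
            for key in node.keys():
                value = node[key]
                if key == "triples":
                    for triple in value:
                        if len(triple) == 3:
                            total += _oracle_path_len(triple[1])
                else:
                    stack.append(value)
        elif isinstance(node, (list, tuple, set, pyparsing.ParseResults)):
            stack.extend(list(node))
    return total


def oracle_void_counts(graph) -> tuple[int, dict[str, int]]:
    """(total triples, per-predicate counts) by direct enumeration."""
    per_predicate: dict[str, int] = {}
    total = 0
    for _s, p, _o in graph:
        total += 1
        per_predicate[str(p)] = per_predicate.get(str(p), 0) + 1
    return total, per_predicate
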