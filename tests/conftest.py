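from __future__ import annotations

import pytest

from rdfstruct.fixtures import FixtureSpec, Multiplicity, ObjectKind, PredicateSpec, paper_examples
from rdfstruct.rdf import Graph
from rdfstruct.recovery import recover_from_graph
from rdfstruct.source import FileGraph, ResourceHandle


def handle_for(namespaces, limit=None):
    """A file-mode handle (the path is never opened in unit tests)."""
    return ResourceHandle(files=("unused.ttl",), namespaces=tuple(namespaces),
                          limit_per_predicate=limit)


def recover_turtle(turtle: str, namespaces=("http://example.org/",), limit=None):
    handle = handle_for(namespaces, limit)
    g = FileGraph(Graph.parse(turtle), handle.namespaces)
    return recover_from_graph(g, handle)


@pytest.fixture
def examples():
    return paper_examples()


def fixture_spec_grid():
    """A deterministic family of generator specs used by property tests."""
    mults = [
        Multiplicity.ONE_TO_ONE,
        Multiplicity.ONE_OR_MANY,
        Multiplicity.ZERO_OR_ONE,
        Multiplicity.ZERO_OR_MANY,
    ]
    specs = []
    seed = 0
    for depth in (1, 2, 3):
        for branching in (1, 2):
            for kinds in (
                (ObjectKind.CLASS,),
                (ObjectKind.CLASS, ObjectKind.DATATYPE),
                (ObjectKind.CLASS, ObjectKind.EXTERNAL, ObjectKind.INVALID),
            ):
                for fraction_untyped in (0.0, 0.3):
                    preds = tuple(
                        PredicateSpec(
                            f"p{i}", kind, mults[(seed + i) % 4],
                            source_class="C",
                            target_class="C0" if depth > 1 else "C",
                        )
                        for i, kind in enumerate(kinds)
                    )
                    specs.append(
                        FixtureSpec(
                            tree_depth=depth, branching=branching,
                            instances_per_class=(2, 5), predicates=preds,
                            fraction_untyped=fraction_untyped, seed=seed,
                        )
                    )
                    seed += 1
    return specs
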