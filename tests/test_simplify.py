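import pytest

from rdfstruct.model import Multiplicity, ObjectKind, UniqueTypeLink
from rdfstruct.recovery import build_class_tree
from rdfstruct.rdf import IRI, XSD
from rdfstruct.simplify import child_of, shared, simplify, simplify_predicate

from conftest import fixture_spec_grid, recover_turtle

EX = "http://example.org/"
M = Multiplicity
K = ObjectKind


def tree_of(edges, classes=()):
    nodes = {c for e in edges for c in e} | set(classes)
    return build_class_tree([(IRI(c), 0) for c in sorted(nodes)], [(IRI(a), IRI(b)) for a, b in edges])


class TestShared:
    def test_identity(self):
        t = tree_of([("Y1", "Y")])
        assert shared((IRI("Y1"), K.CLASS), (IRI("Y1"), K.CLASS), t) == (IRI("Y1"), K.CLASS)

    def test_siblings_share_parent(self):
        t = tree_of([("Y1", "Y"), ("Y2", "Y")])
        assert shared((IRI("Y1"), K.CLASS), (IRI("Y2"), K.CLASS), t) == (IRI("Y"), K.CLASS)

    def test_ancestor_descendant(self):
        t = tree_of([("Y1", "Y")])
        assert shared((IRI("Y1"), K.CLASS), (IRI("Y"), K.CLASS), t) == (IRI("Y"), K.CLASS)

    def test_unrelated_datatypes(self):
        t = tree_of([])
        a = (IRI(str(XSD.integer)), K.DATATYPE)
        b = (IRI(str(XSD.string)), K.DATATYPE)
        assert shared(a, b, t) is None

    def test_diamond_tie_breaks_lexicographically(self):
        t = tree_of([("C", "A"), ("C", "B"), ("D", "A"), ("D", "B")])
        assert shared((IRI("C"), K.CLASS), (IRI("D"), K.CLASS), t) == (IRI("A"), K.CLASS)

    def test_no_common_ancestor(self):
        t = tree_of([("A1", "A"), ("B1", "B")])
        assert shared((IRI("A1"), K.CLASS), (IRI("B1"), K.CLASS), t) is None

    def test_kind_mismatch_never_shares(self):
        t = tree_of([])
        assert shared((IRI("X"), K.CLASS), (IRI("X"), K.EXTERNAL), t) is None


class TestChildOf:
    def test_reflexive(self):
        t = tree_of([], classes=["X"])
        assert child_of(IRI("X"), IRI("X"), t)

    def test_transitive(self):
        t = tree_of([("X", "Y"), ("Y", "Z")])
        assert child_of(IRI("X"), IRI("Z"), t)

    def test_siblings_false(self):
        t = tree_of([("A", "P"), ("B", "P")])
        assert not child_of(IRI("A"), IRI("B"), t)


def _link(s, o, kind=K.CLASS, count=1, fwd=M.ONE_TO_ONE, rev=M.ONE_TO_ONE, pred="p"):
    return UniqueTypeLink(IRI(s), IRI(pred), IRI(o), kind, count, fwd, rev)


class TestSimplifyPredicate:
    def test_case_a(self):
        t = tree_of([("Y1", "Y"), ("Y2", "Y")], classes=["X"])
        out = simplify_predicate([_link("X", "Y1"), _link("X", "Y2")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("X"), IRI("Y"))]
        assert out[0].count == 2

    def test_case_b(self):
        t = tree_of([("X1", "X"), ("X2", "X")], classes=["Y"])
        out = simplify_predicate([_link("X1", "Y"), _link("X2", "Y")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("X"), IRI("Y"))]

    def test_case_c(self):
        t = tree_of([("X1", "X"), ("X2", "X"), ("Y1", "Y"), ("Y2", "Y")])
        out = simplify_predicate([_link("X1", "Y1"), _link("X2", "Y2")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("X"), IRI("Y"))]

    def test_single_link_not_lifted(self):
        # X1 is the only child of X: the copied link at X covers exactly one
        # child and is dropped, the seed at X1 survives
        t = tree_of([("X1", "X")], classes=["Y"])
        out = simplify_predicate([_link("X1", "Y")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("X1"), IRI("Y"))]

    def test_seeded_parent_link_survives_single_child(self):
        # both X and its single child X1 carry the link: the X link is backed
        # by instances of X itself and must not be pushed down
        t = tree_of([("X1", "X")], classes=["Y"])
        out = simplify_predicate([_link("X", "Y", count=2), _link("X1", "Y")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("X"), IRI("Y"))]
        assert out[0].count == 3

    def test_mixed_kinds_do_not_merge(self):
        t = tree_of([], classes=["X"])
        links = [
            _link("X", str(XSD.string), kind=K.DATATYPE),
            _link("X", "http://other.org/", kind=K.EXTERNAL),
        ]
        out = simplify_predicate(links, t)
        assert len(out) == 2

    def test_identical_non_class_targets_merge(self):
        t = tree_of([("X1", "X"), ("X2", "X")])
        links = [
            _link("X1", str(XSD.string), kind=K.DATATYPE),
            _link("X2", str(XSD.string), kind=K.DATATYPE),
        ]
        out = simplify_predicate(links, t)
        assert [(l.subject_type, l.object_type) for l in out] == [
            (IRI("X"), IRI(str(XSD.string)))
        ]

    def test_multiplicity_widened(self):
        t = tree_of([("Y1", "Y"), ("Y2", "Y")], classes=["X"])
        out = simplify_predicate(
            [_link("X", "Y1", fwd=M.ONE_TO_ONE), _link("X", "Y2", fwd=M.ZERO_OR_MANY)], t
        )
        assert out[0].forward == M.ZERO_OR_MANY

    def test_mixed_predicates_rejected(self):
        t = tree_of([], classes=["X"])
        with pytest.raises(ValueError):
            simplify_predicate([_link("X", "X", pred="p"), _link("X", "X", pred="q")], t)

    def test_sameas_group_merges_as_one_node(self):
        t = tree_of([("A", "B"), ("B", "A")], classes=["Y"])
        out = simplify_predicate([_link("A", "Y"), _link("B", "Y")], t)
        assert [(l.subject_type, l.object_type) for l in out] == [(IRI("A"), IRI("Y"))]
        assert out[0].count == 2


def _simplifiable_structures():
    from rdfstruct.fixtures import generate
    from rdfstruct.source import FileGraph
    from rdfstruct.recovery import recover_from_graph
    from rdfstruct.rdf import Graph
    from conftest import handle_for
    from rdfstruct.fixtures import NS

    structures = []
    for spec in fixture_spec_grid()[::4]:
        turtle, _ = generate(spec)
        handle = handle_for((NS,))
        structures.append(recover_from_graph(FileGraph(Graph.parse(turtle), (NS,)), handle))
    return structures


@pytest.fixture(scope="module")
def structures():
    return _simplifiable_structures()


class TestSimplifyProperties:
    def test_idempotent(self, structures):
        for s in structures:
            once = simplify(s)
            assert simplify(once) == once

    def test_count_conservation_per_predicate(self, structures):
        for s in structures:
            out = simplify(s)
            for pred in s.predicates:
                before = sum(l.count for l in s.links_for(pred))
                after = sum(l.count for l in out.links_for(pred))
                assert after == before

    def test_non_expansion(self, structures):
        for s in structures:
            out = simplify(s)
            for pred in s.predicates:
                assert len(out.links_for(pred)) <= len(s.links_for(pred))

    def test_coverage_preservation(self, structures):
        for s in structures:
            out = simplify(s)
            tree = s.class_tree
            for orig in s.links:
                assert any(
                    surv.predicate == orig.predicate
                    and tree.child_of(orig.subject_type, surv.subject_type)
                    and surv.object_kind == orig.object_kind
                    and (
                        tree.child_of(orig.object_type, surv.object_type)
                        if orig.object_kind == K.CLASS
                        else surv.object_type == orig.object_type
                    )
                    for surv in out.links
                ), f"lost coverage of {orig}"

    def test_deterministic(self, structures):
        for s in structures:
            a = simplify(s)
            b = simplify(s)
            assert a == b and a.links == b.links

    def test_no_hierarchy_is_identity(self):
        s = recover_turtle(f"@prefix : <{EX}> . :s a :A ; :p :o . :o a :B .")
        assert simplify(s).links == s.links

    def test_simplification_reduces_links(self, examples):
        for name in ("fig2_case_a", "fig2_case_b", "fig2_case_c"):
            s = recover_turtle(examples[name].turtle)
            assert len(simplify(s).links) < len(s.links)
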