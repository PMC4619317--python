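import xml.etree.ElementTree as ET

import pytest

from rdfstruct import exporters
from rdfstruct.exporters.structure_rdf import SchemaError, from_graph, to_graph
from rdfstruct.exporters.xgmml import build_document, visible_types
from rdfstruct.model import (
    ClassTree,
    Multiplicity,
    ObjectKind,
    StructureGraph,
    UniqueTypeLink,
)
from rdfstruct.rdf import Graph, IRI, OWL, RDF, RDFS, XSD
from rdfstruct.simplify import simplify

from conftest import recover_turtle
from shexc import all_constraints, parse_shexc

EX = "http://example.org/"
M = Multiplicity
K = ObjectKind


def empty_structure():
    return StructureGraph(class_tree=ClassTree(), links=())


def self_link_structure():
    tree = ClassTree()
    tree.add_class(IRI(EX + "A"), 2)
    return StructureGraph(
        class_tree=tree,
        links=(
            UniqueTypeLink(
                IRI(EX + "A"), IRI(EX + "p"), IRI(EX + "A"), K.CLASS,
                count=2, forward=M.ONE_TO_ONE, reverse=M.ONE_TO_ONE,
            ),
        ),
    )


@pytest.fixture
def gene_structure(examples):
    return recover_turtle(examples["gene_chromosome"].turtle)


@pytest.fixture
def rich_structure():
    ttl = f"""
    @prefix : <{EX}> .
    @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
    :SubGene rdfs:subClassOf :Gene .
    :Concept rdfs:subClassOf :Gene .
    :g1 a :Gene ; :locatedOn :c1 ; :name "brca" ; :xref <http://other.org/id/1> ;
        :broken :orphan1 .
    :c1 a :Chromosome .
    """
    return recover_turtle(ttl)


class TestStructureRdfRoundTrip:
    def test_empty(self, tmp_path):
        path = tmp_path / "s.ttl"
        exporters.export_structure_rdf(empty_structure(), str(path))
        assert exporters.import_structure_rdf(str(path)) == empty_structure()

    def test_self_link_budget(self):
        g = to_graph(self_link_structure())
        # 2 triples for the class plus at most 8 for the link
        assert len(g) <= 2 * 1 + 8
        assert len(g) >= 3

    def test_round_trip_gene(self, gene_structure, tmp_path):
        path = tmp_path / "s.ttl"
        exporters.export_structure_rdf(gene_structure, str(path))
        assert exporters.import_structure_rdf(str(path)) == gene_structure

    def test_round_trip_rich(self, rich_structure, tmp_path):
        path = tmp_path / "s.ttl"
        exporters.export_structure_rdf(rich_structure, str(path))
        back = exporters.import_structure_rdf(str(path))
        assert back == rich_structure
        assert back.class_tree.concepts == rich_structure.class_tree.concepts

    def test_budget_exact(self, rich_structure):
        s = rich_structure
        g = to_graph(s)
        n_classes = len(s.class_tree.classes)
        n_edges = len(s.class_tree.edges)
        n_props = len(s.class_properties)
        link_triples = sum(
            6 if l.reverse is not M.NOT_DETERMINED else 5 for l in s.links
        )
        assert len(g) == 2 * n_classes + n_edges + 2 * n_props + link_triples
        assert 2 * n_props + link_triples <= 8 * len(s.links)

    def test_missing_vocabulary_field_is_schema_error(self, gene_structure):
        from rdfstruct.rdf import STRUCT

        g = to_graph(gene_structure)
        cut = Graph((s, p, o) for s, p, o in g if p != STRUCT.instanceCount)
        with pytest.raises(SchemaError, match="instanceCount"):
            from_graph(cut)

    def test_truncated_file_is_an_error(self, gene_structure, tmp_path):
        path = tmp_path / "s.ttl"
        exporters.export_structure_rdf(gene_structure, str(path))
        text = path.read_text()
        (tmp_path / "cut.ttl").write_text(text[: len(text) // 2])
        with pytest.raises(ValueError):  # parse or schema error
            exporters.import_structure_rdf(str(tmp_path / "cut.ttl"))

    def test_missing_reverse_defaults_to_not_determined(self, gene_structure, tmp_path):
        g = to_graph(gene_structure)
        from rdfstruct.rdf import STRUCT

        older = Graph(
            (s, p, o) for s, p, o in g if p != STRUCT.reverseMultiplicity
        )
        back = from_graph(older)
        assert all(l.reverse is M.NOT_DETERMINED for l in back.links)


class TestXgmml:
    def test_gene_network(self, gene_structure, tmp_path):
        path = tmp_path / "g.xgmml"
        exporters.export_xgmml(gene_structure, str(path))
        root = ET.parse(path).getroot()
        nodes = root.findall("{http://www.cs.rpi.edu/XGMML}node")
        edges = root.findall("{http://www.cs.rpi.edu/XGMML}edge")
        assert len(nodes) == 2
        assert len(edges) == 1
        atts = {a.get("name"): a.get("value") for a in edges[0]}
        assert atts["forward"] == "1..1"
        assert atts["reverse"] == "1..N"
        assert atts["kind"] == "typelink"

    def test_hide_datatypes(self, rich_structure):
        shown = build_document(rich_structure, hide_datatypes=False)
        hidden = build_document(rich_structure, hide_datatypes=True)
        iris_shown = {n.get("label") for n in shown.findall("node")}
        iris_hidden = {n.get("label") for n in hidden.findall("node")}
        assert str(XSD.string) in iris_shown
        assert str(XSD.string) not in iris_hidden
        # the edge to the datatype disappears with its node
        assert len(hidden.findall("edge")) < len(shown.findall("edge"))

    def test_hide_concepts(self, rich_structure):
        doc = build_document(rich_structure, hide_concepts=True)
        labels = {n.get("label") for n in doc.findall("node")}
        assert EX + "Concept" not in labels
        assert EX + "SubGene" not in labels  # also instance-free all the way down
        assert EX + "Gene" in labels

    def test_empty_structure_valid(self, tmp_path):
        path = tmp_path / "empty.xgmml"
        exporters.export_xgmml(empty_structure(), str(path))
        root = ET.parse(path).getroot()
        assert root.tag.endswith("graph")
        assert len(root) == 0

    def test_node_count_equals_non_hidden_types(self, rich_structure):
        for hc in (False, True):
            for hd in (False, True):
                doc = build_document(rich_structure, hide_concepts=hc, hide_datatypes=hd)
                assert len(doc.findall("node")) == len(
                    visible_types(rich_structure, hc, hd)
                )

    def test_edges_reference_existing_nodes(self, rich_structure):
        doc = build_document(rich_structure)
        ids = {n.get("id") for n in doc.findall("node")}
        for edge in doc.findall("edge"):
            assert edge.get("source") in ids
            assert edge.get("target") in ids

    def test_stable_ids(self, gene_structure):
        a = ET.tostring(build_document(gene_structure))
        b = ET.tostring(build_document(gene_structure))
        assert a == b


class TestOwl:
    def test_one_to_one_restrictions(self, gene_structure, tmp_path):
        path = tmp_path / "o.owl"
        exporters.export_owl(gene_structure, str(path))
        g = Graph.parse_file(str(path), format="rdfxml")
        restrictions = g.subjects(RDF.type, OWL.Restriction)
        assert len(restrictions) == 2  # allValuesFrom + qualified cardinality
        assert any(g.value(r, OWL.allValuesFrom) == IRI(EX + "Chromosome") for r in restrictions)
        assert any(g.value(r, OWL.qualifiedCardinality) is not None for r in restrictions)

    def test_zero_or_many_has_no_cardinality(self, examples, tmp_path):
        s = recover_turtle(examples["person_hasson"].turtle)
        path = tmp_path / "o.owl"
        exporters.export_owl(s, str(path))
        g = Graph.parse_file(str(path), format="rdfxml")
        restrictions = g.subjects(RDF.type, OWL.Restriction)
        assert len(restrictions) == 1  # allValuesFrom only
        assert g.value(restrictions[0], OWL.allValuesFrom) == IRI(EX + "Person")

    def test_parse_reserialize_lossless(self, rich_structure, tmp_path):
        path = tmp_path / "o.owl"
        exporters.export_owl(rich_structure, str(path), include_inverse=True)
        g1 = Graph.parse_file(str(path), format="rdfxml")
        g2 = Graph.parse(g1.serialize("rdfxml"), "rdfxml")
        assert g1 == g2

    def test_invalid_links_skipped(self, rich_structure, tmp_path):
        path = tmp_path / "o.owl"
        exporters.export_owl(rich_structure, str(path))
        text = path.read_text()
        assert "broken" not in text  # the invalid-target predicate is absent

    def test_property_kinds(self, rich_structure, tmp_path):
        path = tmp_path / "o.owl"
        exporters.export_owl(rich_structure, str(path))
        g = Graph.parse_file(str(path), format="rdfxml")
        assert IRI(EX + "name") in g.subjects(RDF.type, OWL.DatatypeProperty)
        assert IRI(EX + "locatedOn") in g.subjects(RDF.type, OWL.ObjectProperty)
        assert IRI(EX + "xref") in g.subjects(RDF.type, OWL.ObjectProperty)

    def test_subclass_axioms_copied(self, rich_structure, tmp_path):
        path = tmp_path / "o.owl"
        exporters.export_owl(rich_structure, str(path))
        g = Graph.parse_file(str(path), format="rdfxml")
        assert (IRI(EX + "SubGene"), RDFS.subClassOf, IRI(EX + "Gene")) in g

    def test_inverse_restrictions_flagged(self, gene_structure, tmp_path):
        without = tmp_path / "a.owl"
        with_inv = tmp_path / "b.owl"
        exporters.export_owl(gene_structure, str(without), include_inverse=False)
        exporters.export_owl(gene_structure, str(with_inv), include_inverse=True)
        g0 = Graph.parse_file(str(without), format="rdfxml")
        g1 = Graph.parse_file(str(with_inv), format="rdfxml")
        assert len(g0.subjects(OWL.inverseOf)) == 0
        assert len(g1.subjects(OWL.inverseOf)) == 1


class TestShex:
    def test_gene_shape(self, gene_structure):
        text = exporters.serialize_shex(gene_structure)
        shapes = {s.label: s for s in parse_shexc(text)}
        assert set(shapes) == {EX + "Gene", EX + "Chromosome"}
        (c,) = all_constraints(shapes[EX + "Gene"])
        assert c.predicate == EX + "locatedOn"
        assert c.value_kind == "shape" and c.value == EX + "Chromosome"
        assert c.cardinality == ""  # 1..1

    def test_cardinality_mapping(self):
        ttl = f"""
        @prefix : <{EX}> .
        :a a :A ; :one "x" ; :many "p", "q" ; :opt "y" .
        :b a :A ; :one "z" ; :many "r" .
        """
        s = recover_turtle(ttl)
        shapes = {sh.label: sh for sh in parse_shexc(exporters.serialize_shex(s))}
        cards = {c.predicate: c.cardinality for c in all_constraints(shapes[EX + "A"])}
        assert cards[EX + "one"] == ""      # 1..1
        assert cards[EX + "opt"] == "?"     # 0..1
        assert cards[EX + "many"] == "+"    # 1..N

    def test_or_group(self):
        ttl = f"""
        @prefix : <{EX}> .
        :x a :X ; :p :y1 . :y1 a :Y1 .
        :x2 a :X ; :p :y2 . :y2 a :Y2 .
        """
        s = recover_turtle(ttl)
        text = exporters.serialize_shex(s)
        shapes = {sh.label: sh for sh in parse_shexc(text)}
        groups = [i for i in shapes[EX + "X"].constraints if isinstance(i, list)]
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_optional_literal(self):
        ttl = f"@prefix : <{EX}> . :a a :A ; :p \"x\" . :b a :A ."
        s = recover_turtle(ttl)
        shapes = {sh.label: sh for sh in parse_shexc(exporters.serialize_shex(s))}
        (c,) = all_constraints(shapes[EX + "A"])
        assert c.value_kind == "datatype" and c.cardinality == "?"

    def test_invalid_target_nodekind_with_warning(self):
        ttl = f"@prefix : <{EX}> . :a a :A ; :p :orphan ."
        s = recover_turtle(ttl)
        text = exporters.serialize_shex(s)
        shapes = {sh.label: sh for sh in parse_shexc(text)}
        (c,) = all_constraints(shapes[EX + "A"])
        assert c.value_kind == "nodekind" and c.cardinality == "*"
        assert "not determined" in text

    def test_shapes_only_for_instantiated_classes(self, rich_structure):
        shapes = parse_shexc(exporters.serialize_shex(rich_structure))
        tree = rich_structure.class_tree
        for sh in shapes:
            assert tree.instance_count(IRI(sh.label)) > 0


class TestIntegrityReport:
    def test_clean(self, gene_structure, tmp_path):
        path = tmp_path / "r.txt"
        findings = exporters.integrity_report(gene_structure, str(path))
        assert findings == []
        assert path.read_text().startswith("0 issues")

    def test_cds(self, examples, tmp_path):
        s = recover_turtle(examples["cds_collision"].turtle)
        path = tmp_path / "r.txt"
        findings = exporters.integrity_report(s, str(path))
        assert len(findings) == 1
        assert "predicate_also_class" in path.read_text()

    def test_sorted_and_counted(self, rich_structure, tmp_path):
        path = tmp_path / "r.txt"
        findings = exporters.integrity_report(rich_structure, str(path))
        text = path.read_text()
        assert text.startswith(f"{len(findings)} issues")
        assert findings == sorted(findings)
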