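"""Turtle serialization of a StructureGraph under a dedicated vocabulary.

Encoding budget (kept deliberately tight so output size is predictable):
exactly two triples per class (type declaration + instance count), one
triple per subClassOf edge, two triples per class property (owner link +
predicate) and six per unique type link — so at most eight triples are
attributable to each link.  Concept flags and class-property occurrence
totals are recomputed on import rather than stored.
"""

from __future__ import annotations

from ..model import (
    ClassProperty,
    ClassTree,
    Multiplicity,
    ObjectKind,
    StructureGraph,
    UniqueTypeLink,
)
from ..rdf import Graph, IRI, Literal, RDF, RDFS, STRUCT, XSD, BNode
from ..recovery import build_class_tree, detect_concept_classes

_PREFIXES = {
    "rs": str(STRUCT),
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": str(XSD),
}


class SchemaError(ValueError):
    """A structure-RDF file violates the export vocabulary."""


def _int(n: int) -> Literal:
    return Literal(str(n), datatype=XSD.integer)


def to_graph(s: StructureGraph) -> Graph:
    g = Graph()
    tree = s.class_tree
    for cls in tree.classes:
        g.add(cls, RDF.type, STRUCT.Class)
        g.add(cls, STRUCT.instanceCount, _int(tree.instance_count(cls)))
    for child, parent in tree.edges:
        g.add(child, RDFS.subClassOf, parent)
    n_cp = n_l = 0
    for cp in s.class_properties:
        n_cp += 1
        cp_node = BNode(f"cp{n_cp}")
        g.add(cp.owner_class, STRUCT.classProperty, cp_node)
        g.add(cp_node, STRUCT.predicate, cp.predicate)
        for link in cp.links:
            n_l += 1
            l_node = BNode(f"l{n_l}")
            g.add(cp_node, STRUCT.link, l_node)
            g.add(l_node, STRUCT.objectType, link.object_type)
            g.add(l_node, STRUCT.objectKind, Literal(link.object_kind.value))
            g.add(l_node, STRUCT.count, _int(link.count))
            g.add(l_node, STRUCT.forwardMultiplicity, Literal(link.forward.value))
            if link.reverse is not Multiplicity.NOT_DETERMINED:
                g.add(l_node, STRUCT.reverseMultiplicity, Literal(link.reverse.value))
    return g


def export_structure_rdf(s: StructureGraph, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_graph(s).serialize("turtle", prefixes=_PREFIXES))


def from_graph(g: Graph) -> StructureGraph:
    classes = []
    class_set = set()
    for cls in g.subjects(RDF.type, STRUCT.Class):
        count_term = g.value(cls, STRUCT.instanceCount)
        if count_term is None:
            raise SchemaError(f"class <{cls}> has no rs:instanceCount")
        classes.append((cls, int(str(count_term))))
        class_set.add(cls)
    edges = [
        (s, o)
        for s, _, o in g.triples(None, RDFS.subClassOf, None)
        if s in class_set and o in class_set
    ]
    tree = detect_concept_classes(build_class_tree(classes, edges))

    links = []
    for owner, _, cp_node in g.triples(None, STRUCT.classProperty, None):
        if owner not in class_set:
            raise SchemaError(f"class property owner <{owner}> is not a declared class")
        predicate = g.value(cp_node, STRUCT.predicate)
        if predicate is None:
            raise SchemaError(f"class property node {cp_node} has no rs:predicate")
        for _, _, l_node in g.triples(cp_node, STRUCT.link, None):
            object_type = g.value(l_node, STRUCT.objectType)
            kind = g.value(l_node, STRUCT.objectKind)
            count = g.value(l_node, STRUCT.count)
            forward = g.value(l_node, STRUCT.forwardMultiplicity)
            if None in (object_type, kind, count, forward):
                raise SchemaError(f"link node {l_node} is missing required fields")
            reverse = g.value(l_node, STRUCT.reverseMultiplicity)
            try:
                okind = ObjectKind(str(kind))
                fwd = Multiplicity(str(forward))
                rev = (
                    Multiplicity(str(reverse))
                    if reverse is not None
                    else Multiplicity.NOT_DETERMINED
                )
            except ValueError as exc:
                raise SchemaError(f"link node {l_node}: {exc}") from exc
            links.append(
                UniqueTypeLink(
                    IRI(str(owner)), IRI(str(predicate)), IRI(str(object_type)),
                    okind, count=int(str(count)), forward=fwd, reverse=rev,
                )
            )
    return StructureGraph(class_tree=tree, links=tuple(sorted(links)))


def import_structure_rdf(path: str) -> StructureGraph:
    return from_graph(Graph.parse_file(path, format="turtle"))
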