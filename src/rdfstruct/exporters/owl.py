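"""OWL 2 (RDF/XML) export of a recovered structure.

Per predicate an object or data property with union domain/range; per class
property an allValuesFrom restriction (an owl:unionOf when the property
holds several links) plus a qualified-cardinality axiom derived from the
forward multiplicity; optionally the same restrictions for the inverse
property derived from the reverse multiplicity.  Links to invalid subjects
have no OWL counterpart and are skipped (logged).
"""

from __future__ import annotations

import logging

from ..model import Multiplicity, ObjectKind, StructureGraph
from ..rdf import Graph, IRI, Literal, OWL, RDF, RDFS, XSD, BNode

logger = logging.getLogger(__name__)

_NNI = "http://www.w3.org/2001/XMLSchema#nonNegativeInteger"


class _Minting:
    def __init__(self):
        self.n = 0

    def bnode(self) -> BNode:
        self.n += 1
        return BNode(f"n{self.n}")


def _rdf_list(g: Graph, items, mint: _Minting):
    if not items:
        return RDF.nil
    head = mint.bnode()
    node = head
    for i, item in enumerate(items):
        g.add(node, RDF.first, item)
        if i == len(items) - 1:
            g.add(node, RDF.rest, RDF.nil)
        else:
            nxt = mint.bnode()
            g.add(node, RDF.rest, nxt)
            node = nxt
    return head


def _union(g: Graph, items, mint: _Minting):
    items = sorted(set(items))
    if len(items) == 1:
        return items[0]
    node = mint.bnode()
    g.add(node, RDF.type, OWL.Class)
    g.add(node, OWL.unionOf, _rdf_list(g, items, mint))
    return node


_CARD = {
    Multiplicity.ONE_TO_ONE: ("qualifiedCardinality", 1),
    Multiplicity.ONE_OR_MANY: ("minQualifiedCardinality", 1),
    Multiplicity.ZERO_OR_ONE: ("maxQualifiedCardinality", 1),
    Multiplicity.ZERO_OR_MANY: None,
    Multiplicity.NOT_DETERMINED: None,
}


def _restriction(g, mint, on_property, owner, target, is_datatype, mult):
    """Attach allValuesFrom + cardinality restrictions for one class property."""
    r = mint.bnode()
    g.add(r, RDF.type, OWL.Restriction)
    g.add(r, OWL.onProperty, on_property)
    g.add(r, OWL.allValuesFrom, target)
    g.add(owner, RDFS.subClassOf, r)
    card = _CARD[mult]
    if card is not None:
        name, n = card
        c = mint.bnode()
        g.add(c, RDF.type, OWL.Restriction)
        g.add(c, OWL.onProperty, on_property)
        g.add(c, OWL[name], Literal(str(n), datatype=_NNI))
        g.add(c, OWL.onDataRange if is_datatype else OWL.onClass, target)
        g.add(owner, RDFS.subClassOf, c)


def to_graph(s: StructureGraph, include_inverse: bool = False) -> Graph:
    g = Graph()
    mint = _Minting()
    tree = s.class_tree
    g.add(IRI("urn:rdfstruct:ontology"), RDF.type, OWL.Ontology)
    for cls in tree.classes:
        g.add(cls, RDF.type, OWL.Class)
    for child, parent in tree.edges:
        g.add(child, RDFS.subClassOf, parent)

    usable = [l for l in s.links if l.object_kind is not ObjectKind.INVALID]
    for link in s.links:
        if link.object_kind is ObjectKind.INVALID:
            logger.info("skipping link with invalid target in OWL export: %s", link)

    # property declarations with union domains/ranges
    by_pred: dict[IRI, list] = {}
    for link in usable:
        by_pred.setdefault(link.predicate, []).append(link)
    for pred in sorted(by_pred):
        links = by_pred[pred]
        is_data = all(l.object_kind is ObjectKind.DATATYPE for l in links)
        g.add(pred, RDF.type, OWL.DatatypeProperty if is_data else OWL.ObjectProperty)
        g.add(pred, RDFS.domain, _union(g, [l.subject_type for l in links], mint))
        g.add(pred, RDFS.range, _union(g, [l.object_type for l in links], mint))

    # per-class-property restrictions
    for cp in s.class_properties:
        links = [l for l in cp.links if l.object_kind is not ObjectKind.INVALID]
        if not links:
            continue
        is_data = all(l.object_kind is ObjectKind.DATATYPE for l in links)
        target = _union(g, [l.object_type for l in links], mint)
        from ..model import aggregate_multiplicity

        _restriction(
            g, mint, cp.predicate, cp.owner_class, target, is_data,
            aggregate_multiplicity([l.forward for l in links]),
        )
        if include_inverse:
            for link in links:
                if link.object_kind is not ObjectKind.CLASS:
                    continue
                if link.reverse is Multiplicity.NOT_DETERMINED:
                    continue
                inv = mint.bnode()
                g.add(inv, OWL.inverseOf, cp.predicate)
                _restriction(
                    g, mint, inv, link.object_type, link.subject_type, False,
                    link.reverse,
                )
    return g


def export_owl(s: StructureGraph, path: str, include_inverse: bool = False) -> None:
    g = to_graph(s, include_inverse=include_inverse)
    prefixes = {
        "owl": str(OWL),
        "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
        "xsd": str(XSD),
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(g.serialize("rdfxml", prefixes=prefixes))
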