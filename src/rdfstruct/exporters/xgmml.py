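"""XGMML (Cytoscape 3.x) network export.

One node per type — classes, plus the datatype/external/invalid targets of
surviving links — and one edge per unique type link and per direct
subClassOf pair.  Node ids are stable hashes of the IRIs so re-exports diff
cleanly.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET

from ..model import ObjectKind, StructureGraph

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def node_id(iri: str) -> int:
    return int(hashlib.sha1(iri.encode("utf-8")).hexdigest()[:12], 16)


def _att(parent, name: str, value, att_type: str = "string") -> None:
    ET.SubElement(parent, "att", name=name, value=str(value), type=att_type)


def visible_types(
    s: StructureGraph, hide_concepts: bool, hide_datatypes: bool
) -> dict[str, ObjectKind]:
    """The types shown in the network, with their node kind."""
    types: dict[str, ObjectKind] = {}
    tree = s.class_tree
    for cls in tree.classes:
        if hide_concepts and tree.is_concept(cls):
            continue
        types[str(cls)] = ObjectKind.CLASS
    for link in s.links:
        if link.object_kind is ObjectKind.CLASS:
            continue
        if hide_datatypes and link.object_kind is ObjectKind.DATATYPE:
            continue
        types[str(link.object_type)] = link.object_kind
    return types


def build_document(
    s: StructureGraph,
    hide_concepts: bool = False,
    hide_datatypes: bool = False,
    label: str = "recovered structure",
) -> ET.Element:
    root = ET.Element("graph", {"label": label, "directed": "1", "xmlns": _XGMML_NS})
    types = visible_types(s, hide_concepts, hide_datatypes)
    tree = s.class_tree
    for iri in sorted(types):
        kind = types[iri]
        node = ET.SubElement(root, "node", id=str(node_id(iri)), label=iri)
        _att(node, "iri", iri)
        _att(node, "kind", kind.value)
        if kind is ObjectKind.CLASS:
            _att(node, "instances", tree.instance_count(iri), "integer")
            _att(node, "concept", "1" if tree.is_concept(iri) else "0", "boolean")
    for link in sorted(s.links):
        if str(link.subject_type) not in types or str(link.object_type) not in types:
            continue
        edge = ET.SubElement(
            root,
            "edge",
            source=str(node_id(str(link.subject_type))),
            target=str(node_id(str(link.object_type))),
            label=str(link.predicate),
        )
        _att(edge, "kind", "typelink")
        _att(edge, "predicate", str(link.predicate))
        _att(edge, "count", link.count, "integer")
        _att(edge, "forward", link.forward.value)
        _att(edge, "reverse", link.reverse.value)
    for child, parent in tree.edges:
        if str(child) not in types or str(parent) not in types:
            continue
        edge = ET.SubElement(
            root,
            "edge",
            source=str(node_id(str(child))),
            target=str(node_id(str(parent))),
            label="subClassOf",
        )
        _att(edge, "kind", "subClassOf")
    return root


def export_xgmml(
    s: StructureGraph,
    path: str,
    hide_concepts: bool = False,
    hide_datatypes: bool = False,
) -> None:
    root = build_document(s, hide_concepts, hide_datatypes)
    ET.indent(root)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write(ET.tostring(root, encoding="unicode"))
        fh.write("\n")
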