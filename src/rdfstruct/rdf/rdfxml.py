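"""RDF/XML reader/writer built on ``xml.etree``.

Covers the striped-syntax core: node elements (``rdf:Description`` or typed),
``rdf:about``/``rdf:ID``/``rdf:nodeID``, property elements with
``rdf:resource``/``rdf:nodeID``/``rdf:datatype``/``xml:lang``, nested node
elements, and ``rdf:parseType="Resource"``/``"Collection"``.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from xml.sax.saxutils import escape as xml_escape, quoteattr

from . import graph as _graph
from .namespaces import RDF
from .terms import BNode, IRI, Literal, sort_key

_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_XML_NS = "http://www.w3.org/XML/1998/namespace"


def _q(tag: str) -> str:
    return "{%s}%s" % (_RDF_NS, tag)


def _split(tag: str) -> str:
    """'{ns}local' -> 'nslocal' (the IRI of the element)."""
    if tag.startswith("{"):
        ns, local = tag[1:].split("}", 1)
        return ns + local
    return tag


class _Reader:
    def __init__(self, source: str):
        self.graph = _graph.Graph()
        self.source = source
        self._n = 0

    def _fresh(self) -> BNode:
        self._n += 1
        return BNode(f"x{self._n}")

    def read(self, text: str) -> "_graph.Graph":
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            line = getattr(exc, "position", (0, 0))[0]
            raise _graph.ParseError(str(exc), self.source, line) from exc
        if root.tag == _q("RDF"):
            for child in root:
                self._node_element(child)
        else:
            self._node_element(root)
        return self.graph

    def _subject_of(self, elem) -> IRI | BNode:
        about = elem.get(_q("about"))
        if about is not None:
            return IRI(about)
        rid = elem.get(_q("ID"))
        if rid is not None:
            return IRI("#" + rid)
        node_id = elem.get(_q("nodeID"))
        if node_id is not None:
            return BNode(node_id)
        return self._fresh()

    def _node_element(self, elem) -> IRI | BNode:
        subject = self._subject_of(elem)
        if elem.tag != _q("Description"):
            self.graph.add(subject, RDF.type, IRI(_split(elem.tag)))
        for attr, value in elem.attrib.items():
            if attr.startswith("{%s}" % _RDF_NS) or attr == "{%s}lang" % _XML_NS:
                continue
            self.graph.add(subject, IRI(_split(attr)), Literal(value))
        for prop in elem:
            self._property_element(subject, prop)
        return subject

    def _property_element(self, subject, prop) -> None:
        predicate = IRI(_split(prop.tag))
        resource = prop.get(_q("resource"))
        node_id = prop.get(_q("nodeID"))
        parse_type = prop.get(_q("parseType"))
        datatype = prop.get(_q("datatype"))
        lang = prop.get("{%s}lang" % _XML_NS)
        children = list(prop)

        if resource is not None:
            self.graph.add(subject, predicate, IRI(resource))
        elif node_id is not None:
            self.graph.add(subject, predicate, BNode(node_id))
        elif parse_type == "Resource":
            inner = self._fresh()
            self.graph.add(subject, predicate, inner)
            for sub in children:
                self._property_element(inner, sub)
        elif parse_type == "Collection":
            items = [self._node_element(c) for c in children]
            if not items:
                self.graph.add(subject, predicate, RDF.nil)
                return
            head = self._fresh()
            self.graph.add(subject, predicate, head)
            node = head
            for i, item in enumerate(items):
                self.graph.add(node, RDF.first, item)
                if i == len(items) - 1:
                    self.graph.add(node, RDF.rest, RDF.nil)
                else:
                    nxt = self._fresh()
                    self.graph.add(node, RDF.rest, nxt)
                    node = nxt
        elif parse_type == "Literal":
            text = (prop.text or "") + "".join(
                ET.tostring(c, encoding="unicode") for c in children
            )
            self.graph.add(subject, predicate, Literal(text))
        elif children:
            obj = self._node_element(children[0])
            self.graph.add(subject, predicate, obj)
        else:
            self.graph.add(
                subject, predicate, Literal(prop.text or "", datatype=datatype, lang=lang)
            )


def parse(text: str, source: str = "") -> "_graph.Graph":
    return _Reader(source).read(text)


# ---------------------------------------------------------------------------
# serialization

_NAME_RE = re.compile(r"[A-Za-z_][\w.-]*$")


def _split_iri(iri: str) -> tuple[str, str]:
    """Split an IRI into (namespace, XML-name local part)."""
    m = _NAME_RE.search(iri)
    if m is None or m.start() == 0:
        raise ValueError(f"cannot serialize predicate {iri!r} in RDF/XML")
    # backtrack so the local part is a valid NCName not containing '.' issues
    return iri[: m.start()], iri[m.start():]


def serialize(g: "_graph.Graph", prefixes: dict | None = None) -> str:
    prefixes = dict(prefixes or {})
    prefixes.setdefault("rdf", _RDF_NS)

    ns_to_prefix = {ns: p for p, ns in prefixes.items()}
    extra = 0
    pred_names: dict[str, tuple[str, str]] = {}
    preds = sorted({p for _, p, _ in g} | {RDF.type})
    for pred in preds:
        ns, local = _split_iri(str(pred))
        if ns not in ns_to_prefix:
            extra += 1
            ns_to_prefix[ns] = f"ns{extra}"
        pred_names[str(pred)] = (ns_to_prefix[ns], local)

    lines = ['<?xml version="1.0" encoding="utf-8"?>']
    decls = " ".join(
        f'xmlns:{p}={quoteattr(ns)}'
        for ns, p in sorted(ns_to_prefix.items(), key=lambda kv: kv[1])
    )
    lines.append(f"<rdf:RDF {decls}>")

    by_subject: dict = {}
    for s, p, o in g:
        by_subject.setdefault(s, []).append((p, o))

    for s in sorted(by_subject, key=sort_key):
        if isinstance(s, BNode):
            sattr = f"rdf:nodeID={quoteattr(str(s))}"
        else:
            sattr = f"rdf:about={quoteattr(str(s))}"
        lines.append(f"  <rdf:Description {sattr}>")
        for p, o in sorted(by_subject[s], key=lambda po: (sort_key(po[0]), sort_key(po[1]))):
            prefix, local = pred_names[str(p)]
            tag = f"{prefix}:{local}"
            if isinstance(o, IRI):
                lines.append(f"    <{tag} rdf:resource={quoteattr(str(o))}/>")
            elif isinstance(o, BNode):
                lines.append(f"    <{tag} rdf:nodeID={quoteattr(str(o))}/>")
            else:
                from .terms import XSD_STRING

                attrs = ""
                if o.lang:
                    attrs = f" xml:lang={quoteattr(o.lang)}"
                elif o.datatype and o.datatype != XSD_STRING:
                    attrs = f" rdf:datatype={quoteattr(o.datatype)}"
                lines.append(f"    <{tag}{attrs}>{xml_escape(str(o))}</{tag}>")
        lines.append("  </rdf:Description>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"
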