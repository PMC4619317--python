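"""An in-memory RDF graph with format dispatch.

The graph is a set of triples with deterministic (sorted) iteration.
Supported formats: Turtle, N-Triples and RDF/XML, both directions.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

from .terms import BNode, IRI, Literal, Term, sort_key, triple_key

_EXT_FORMAT = {
    ".ttl": "turtle",
    ".turtle": "turtle",
    ".n3": "turtle",
    ".nt": "ntriples",
    ".rdf": "rdfxml",
    ".owl": "rdfxml",
    ".xml": "rdfxml",
}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries file and line."""

    def __init__(self, message: str, source: str = "", line: int = 0):
        self.source = source
        self.line = line
        loc = f"{source or '<string>'}:{line}: " if line else f"{source or '<string>'}: "
        super().__init__(loc + message)


def format_for_path(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    try:
        return _EXT_FORMAT[ext]
    except KeyError:
        raise ParseError(f"cannot guess RDF format from extension {ext!r}", path) from None


class Graph:
    """A mutable set of RDF triples."""

    def __init__(self, triples: Iterable[tuple] = ()):
        self._triples: set[tuple] = set(triples)

    # -- basic container protocol ------------------------------------
    def add(self, s: Term, p: Term, o: Term) -> None:
        self._triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: tuple) -> bool:
        return triple in self._triples

    def __iter__(self) -> Iterator[tuple]:
        return iter(sorted(self._triples, key=triple_key))

    def __eq__(self, other) -> bool:
        if isinstance(other, Graph):
            return self._triples == other._triples
        return NotImplemented

    def __hash__(self):  # pragma: no cover
        raise TypeError("Graph is unhashable")

    # -- pattern matching --------------------------------------------
    def triples(
        self,
        s: Optional[Term] = None,
        p: Optional[Term] = None,
        o: Optional[Term] = None,
    ) -> Iterator[tuple]:
        """All triples matching the pattern (None = wildcard), sorted."""
        for ts, tp, to in self:
            if s is not None and ts != s:
                continue
            if p is not None and tp != p:
                continue
            if o is not None and to != o:
                continue
            yield (ts, tp, to)

    def subjects(self, p: Optional[Term] = None, o: Optional[Term] = None):
        return sorted({t[0] for t in self.triples(None, p, o)}, key=sort_key)

    def objects(self, s: Optional[Term] = None, p: Optional[Term] = None):
        return sorted({t[2] for t in self.triples(s, p, None)}, key=sort_key)

    def value(self, s: Term, p: Term) -> Optional[Term]:
        for t in self.triples(s, p, None):
            return t[2]
        return None

    # -- i/o -----------------------------------------------------------
    @classmethod
    def parse(cls, text: str, format: str = "turtle", source: str = "") -> "Graph":
        from . import ntriples, rdfxml, turtle

        if format == "turtle":
            return turtle.parse(text, source=source)
        if format == "ntriples":
            return ntriples.parse(text, source=source)
        if format == "rdfxml":
            return rdfxml.parse(text, source=source)
        raise ValueError(f"unknown RDF format {format!r}")

    @classmethod
    def parse_file(cls, path: str, format: Optional[str] = None) -> "Graph":
        fmt = format or format_for_path(path)
        with open(path, "r", encoding="utf-8") as fh:
            return cls.parse(fh.read(), format=fmt, source=path)

    def serialize(self, format: str = "turtle", prefixes: Optional[dict] = None) -> str:
        from . import ntriples, rdfxml, turtle

        if format == "turtle":
            return turtle.serialize(self, prefixes=prefixes)
        if format == "ntriples":
            return ntriples.serialize(self)
        if format == "rdfxml":
            return rdfxml.serialize(self, prefixes=prefixes)
        raise ValueError(f"unknown RDF format {format!r}")

    def skolemize(self, base: str) -> "Graph":
        """Replace blank nodes by IRIs minted under ``base``.

        Labels are assigned in deterministic (sorted) first-seen order, so
        one parsed file always skolemizes the same way.
        """
        mapping: dict[BNode, IRI] = {}
        for node in sorted(
            {t for triple in self._triples for t in triple if isinstance(t, BNode)}
        ):
            mapping[node] = IRI(f"{base}.well-known/genid/{node}")

        def sub(t: Term) -> Term:
            return mapping.get(t, t) if isinstance(t, BNode) else t

        return Graph((sub(s), sub(p), sub(o)) for s, p, o in self._triples)
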