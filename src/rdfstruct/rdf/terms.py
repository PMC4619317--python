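"""RDF term model: IRIs, blank nodes and literals.

Terms are thin ``str`` subclasses so they hash/compare cheaply and can be
used directly as dictionary keys.  A total, deterministic order over all
terms is provided by :func:`sort_key`; every iteration order in this
package derives from it.
"""

from __future__ import annotations

from typing import Union

XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"


class IRI(str):
    """An absolute IRI."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"IRI({str.__repr__(self)})"

    def namespace(self) -> str:
        """Host-level namespace prefix: scheme://authority/ (or up to the
        last '#'/'/' for non-hierarchical IRIs)."""
        s = str(self)
        if "://" in s:
            scheme, rest = s.split("://", 1)
            host = rest.split("/", 1)[0]
            return f"{scheme}://{host}/"
        for sep in ("#", "/", ":"):
            if sep in s:
                return s.rsplit(sep, 1)[0] + sep
        return s


class BNode(str):
    """A blank node label (without the ``_:`` prefix)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return f"BNode({str.__repr__(self)})"


class Literal(str):
    """An RDF literal; the ``str`` value is the lexical form."""

    __slots__ = ("datatype", "lang")

    datatype: str
    lang: str

    def __new__(cls, lexical: str, datatype: str | None = None, lang: str | None = None):
        obj = str.__new__(cls, lexical)
        if lang:
            # language-tagged strings are treated uniformly as strings
            obj.datatype = XSD_STRING
            obj.lang = lang
        else:
            obj.datatype = datatype or XSD_STRING
            obj.lang = ""
        return obj

    def __eq__(self, other) -> bool:
        if isinstance(other, Literal):
            return (
                str(self) == str(other)
                and self.datatype == other.datatype
                and self.lang == other.lang
            )
        return NotImplemented

    def __ne__(self, other) -> bool:
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq

    def __hash__(self) -> int:
        return hash((str(self), self.datatype, self.lang))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Literal({str.__repr__(self)}, datatype={self.datatype!r}, lang={self.lang!r})"


Term = Union[IRI, BNode, Literal]
Triple = tuple  # (subject, predicate, object)


def sort_key(term: Term) -> tuple:
    """Deterministic total order: IRIs < blank nodes < literals."""
    if isinstance(term, Literal):
        return (2, str(term), term.datatype, term.lang)
    if isinstance(term, BNode):
        return (1, str(term))
    return (0, str(term))


def triple_key(t: Triple) -> tuple:
    return (sort_key(t[0]), sort_key(t[1]), sort_key(t[2]))
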