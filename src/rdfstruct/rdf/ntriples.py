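"""N-Triples reader/writer (line-based subset of Turtle)."""

from __future__ import annotations

import re

from .terms import BNode, IRI, Literal
from . import graph as _graph

_IRIREF = r"<([^<>\"{}|^`\\\x00-\x20]*)>"
_BNODE = r"_:([A-Za-z0-9][A-Za-z0-9._-]*)"
_STRING = r'"((?:[^"\\]|\\.)*)"'
_LITERAL = rf'{_STRING}(?:\^\^{_IRIREF}|@([A-Za-z]+(?:-[A-Za-z0-9]+)*))?'

_TRIPLE_RE = re.compile(
    rf"^\s*(?:{_IRIREF}|{_BNODE})\s+{_IRIREF}\s+"
    rf"(?:{_IRIREF}|{_BNODE}|{_LITERAL})\s*\.\s*$"
)

_ESCAPES = {
    "t": "\t",
    "b": "\b",
    "n": "\n",
    "r": "\r",
    "f": "\f",
    '"': '"',
    "'": "'",
    "\\": "\\",
}


def unescape(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c != "\\":
            out.append(c)
            i += 1
            continue
        if i + 1 >= len(s):
            raise ValueError("dangling backslash")
        nxt = s[i + 1]
        if nxt == "u":
            out.append(chr(int(s[i + 2 : i + 6], 16)))
            i += 6
        elif nxt == "U":
            out.append(chr(int(s[i + 2 : i + 10], 16)))
            i += 10
        elif nxt in _ESCAPES:
            out.append(_ESCAPES[nxt])
            i += 2
        else:
            raise ValueError(f"bad escape \\{nxt}")
    return "".join(out)


def escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def parse(text: str, source: str = "") -> "_graph.Graph":
    g = _graph.Graph()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _TRIPLE_RE.match(line)
        if m is None:
            raise _graph.ParseError("malformed N-Triples statement", source, lineno)
        s_iri, s_bn, p_iri, o_iri, o_bn, o_lex, o_dt, o_lang = m.groups()
        s = IRI(unescape(s_iri)) if s_iri is not None else BNode(s_bn)
        p = IRI(unescape(p_iri))
        if o_iri is not None:
            o = IRI(unescape(o_iri))
        elif o_bn is not None:
            o = BNode(o_bn)
        else:
            o = Literal(
                unescape(o_lex),
                datatype=unescape(o_dt) if o_dt else None,
                lang=o_lang,
            )
        g.add(s, p, o)
    return g


def term_nt(t) -> str:
    if isinstance(t, Literal):
        base = f'"{escape(str(t))}"'
        if t.lang:
            return f"{base}@{t.lang}"
        from .terms import XSD_STRING

        if t.datatype and t.datatype != XSD_STRING:
            return f"{base}^^<{t.datatype}>"
        return base
    if isinstance(t, BNode):
        return f"_:{t}"
    return f"<{t}>"


def serialize(g: "_graph.Graph") -> str:
    return "".join(f"{term_nt(s)} {term_nt(p)} {term_nt(o)} .\n" for s, p, o in g)
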