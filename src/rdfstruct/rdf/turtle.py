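"""Turtle reader/writer.

The reader is a hand-written recursive-descent parser covering the Turtle
constructs this package and its fixtures use: prefix/base directives (both
``@prefix`` and SPARQL style), prefixed names, IRIs, blank-node labels and
property lists, collections, object/predicate lists, the ``a`` keyword,
string literals in all four quote styles, numeric and boolean shorthand,
datatyped and language-tagged literals, and comments.
"""

from __future__ import annotations

import re

from . import graph as _graph
from .ntriples import escape, term_nt, unescape
from .terms import BNode, IRI, Literal, sort_key
from .namespaces import RDF, XSD

_TOKEN_RE = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<ws>\s+)
    | (?P<triple_quote>\"\"\"(?:[^"\\]|\\.|"(?!""))*\"\"\"|'''(?:[^'\\]|\\.|'(?!''))*''')
    | (?P<string>"(?:[^"\\\n]|\\.)*"|'(?:[^'\\\n]|\\.)*')
    | (?P<iriref><[^<>"{}|^`\\\x00-\x20]*>)
    | (?P<prefix_decl>@prefix|@base|PREFIX\b|BASE\b)
    | (?P<langtag>@[A-Za-z]+(?:-[A-Za-z0-9]+)*)
    | (?P<double>[+-]?(?:\d+\.\d*|\.\d+|\d+)[eE][+-]?\d+)
    | (?P<decimal>[+-]?\d*\.\d+)
    | (?P<integer>[+-]?\d+)
    | (?P<boolean>(?:true|false)(?![\w:]))
    | (?P<bnode>_:[A-Za-z0-9](?:[A-Za-z0-9._-]*[A-Za-z0-9_-])?)
    | (?P<pname>(?:[A-Za-z_][\w.-]*)?:(?:[\w:._~-]|%[0-9A-Fa-f]{2}|\\[_~.!$&'()*+,;=/?#@%-])*)
    | (?P<punct>\^\^|[;,.\[\]()])
    | (?P<kw_a>a(?=[\s<\[_(]))
""",
    re.VERBOSE,
)

_PN_LOCAL_ESC = re.compile(r"\\([_~.!$&'()*+,;=/?#@%-])")


class _Parser:
    def __init__(self, text: str, source: str = ""):
        self.text = text
        self.source = source
        self.tokens: list[tuple[str, str, int]] = []  # (kind, value, line)
        self.pos = 0
        self.prefixes: dict[str, str] = {}
        self.base = ""
        self.graph = _graph.Graph()
        self._bnode_n = 0
        self._tokenize()

    # -- lexing --------------------------------------------------------
    def _tokenize(self) -> None:
        i, line = 0, 1
        text = self.text
        while i < len(text):
            m = _TOKEN_RE.match(text, i)
            if m is None:
                raise _graph.ParseError(
                    f"unexpected character {text[i]!r}", self.source, line
                )
            kind = m.lastgroup
            value = m.group()
            if kind not in ("ws", "comment"):
                self.tokens.append((kind, value, line))
            line += value.count("\n")
            i = m.end()
        self.tokens.append(("eof", "", line))

    def _peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def _next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _expect(self, kind: str, value: str | None = None) -> tuple[str, str, int]:
        tok = self._next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise _graph.ParseError(
                f"expected {value or kind}, got {tok[1]!r}", self.source, tok[2]
            )
        return tok

    def _fresh_bnode(self) -> BNode:
        self._bnode_n += 1
        return BNode(f"b{self._bnode_n}")

    # -- grammar ---------------------------------------------------------
    def parse(self) -> "_graph.Graph":
        while self._peek()[0] != "eof":
            kind, value, line = self._peek()
            if kind == "prefix_decl":
                self._directive()
            else:
                self._triples_block()
        return self.graph

    def _directive(self) -> None:
        _, decl, line = self._next()
        decl_l = decl.lower().lstrip("@").strip()
        if decl_l == "prefix":
            kind, value, ln = self._next()
            if kind != "pname" or not value.endswith(":"):
                raise _graph.ParseError("expected prefix name", self.source, ln)
            prefix = value[:-1]
            iri = self._expect("iriref")[1]
            self.prefixes[prefix] = self._resolve(iri[1:-1])
            if decl.startswith("@"):
                self._expect("punct", ".")
        elif decl_l == "base":
            iri = self._expect("iriref")[1]
            self.base = self._resolve(iri[1:-1])
            if decl.startswith("@"):
                self._expect("punct", ".")
        else:  # pragma: no cover
            raise _graph.ParseError(f"unknown directive {decl!r}", self.source, line)

    def _resolve(self, iri: str) -> str:
        if self.base and not re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", iri):
            return self.base + iri
        return iri

    def _triples_block(self) -> None:
        subject = self._subject()
        self._predicate_object_list(subject)
        self._expect("punct", ".")

    def _subject(self):
        kind, value, line = self._peek()
        if kind in ("iriref", "pname"):
            return self._iri_term()
        if kind == "bnode":
            self._next()
            return BNode(value[2:])
        if kind == "punct" and value == "[":
            return self._blank_node_property_list()
        if kind == "punct" and value == "(":
            return self._collection()
        raise _graph.ParseError(f"expected subject, got {value!r}", self.source, line)

    def _iri_term(self) -> IRI:
        kind, value, line = self._next()
        if kind == "iriref":
            return IRI(self._resolve(unescape(value[1:-1])))
        prefix, _, local = value.partition(":")
        if prefix not in self.prefixes:
            raise _graph.ParseError(f"undefined prefix {prefix!r}:", self.source, line)
        local = _PN_LOCAL_ESC.sub(r"\1", local)
        return IRI(self.prefixes[prefix] + local)

    def _predicate_object_list(self, subject) -> None:
        while True:
            kind, value, line = self._peek()
            if kind == "kw_a":
                self._next()
                predicate = RDF.type
            elif kind in ("iriref", "pname"):
                predicate = self._iri_term()
            else:
                raise _graph.ParseError(
                    f"expected predicate, got {value!r}", self.source, line
                )
            while True:
                obj = self._object()
                self.graph.add(subject, predicate, obj)
                if self._peek()[:2] == ("punct", ","):
                    self._next()
                    continue
                break
            if self._peek()[:2] == ("punct", ";"):
                self._next()
                # tolerate trailing ';' before '.' or ']'
                if self._peek()[:2] in (("punct", "."), ("punct", "]")):
                    return
                continue
            return

    def _object(self):
        kind, value, line = self._peek()
        if kind in ("iriref", "pname"):
            return self._iri_term()
        if kind == "bnode":
            self._next()
            return BNode(value[2:])
        if kind == "punct" and value == "[":
            return self._blank_node_property_list()
        if kind == "punct" and value == "(":
            return self._collection()
        if kind in ("string", "triple_quote"):
            return self._literal()
        if kind == "integer":
            self._next()
            return Literal(value, datatype=XSD.integer)
        if kind == "decimal":
            self._next()
            return Literal(value, datatype=XSD.decimal)
        if kind == "double":
            self._next()
            return Literal(value, datatype=XSD.double)
        if kind == "boolean":
            self._next()
            return Literal(value, datatype=XSD.boolean)
        raise _graph.ParseError(f"expected object, got {value!r}", self.source, line)

    def _literal(self) -> Literal:
        kind, value, line = self._next()
        lex = value[3:-3] if kind == "triple_quote" else value[1:-1]
        lex = unescape(lex)
        nkind, nvalue, _ = self._peek()
        if nkind == "langtag":
            self._next()
            return Literal(lex, lang=nvalue[1:])
        if nkind == "punct" and nvalue == "^^":
            self._next()
            return Literal(lex, datatype=str(self._iri_term()))
        return Literal(lex)

    def _blank_node_property_list(self) -> BNode:
        self._expect("punct", "[")
        node = self._fresh_bnode()
        if self._peek()[:2] != ("punct", "]"):
            self._predicate_object_list(node)
        self._expect("punct", "]")
        return node

    def _collection(self):
        self._expect("punct", "(")
        items = []
        while self._peek()[:2] != ("punct", ")"):
            items.append(self._object())
        self._next()
        if not items:
            return RDF.nil
        head = self._fresh_bnode()
        node = head
        for i, item in enumerate(items):
            self.graph.add(node, RDF.first, item)
            if i == len(items) - 1:
                self.graph.add(node, RDF.rest, RDF.nil)
            else:
                nxt = self._fresh_bnode()
                self.graph.add(node, RDF.rest, nxt)
                node = nxt
        return head


def parse(text: str, source: str = "") -> "_graph.Graph":
    return _Parser(text, source=source).parse()


# ---------------------------------------------------------------------------
# serialization


def _curie(iri: str, prefixes: dict[str, str]) -> str | None:
    best_prefix, best_ns = None, ""
    for prefix, ns in sorted(prefixes.items()):
        if not iri.startswith(ns) or len(ns) <= len(best_ns):
            continue
        local = iri[len(ns):]
        if (
            re.fullmatch(r"[\w.-]*", local)
            and not local.startswith((".", "-"))
            and not local.endswith(".")
        ):
            best_prefix, best_ns = prefix, ns
    if best_prefix is None:
        return None
    return f"{best_prefix}:{iri[len(best_ns):]}"


def _term_ttl(t, prefixes: dict[str, str]) -> str:
    if isinstance(t, Literal):
        dt = _curie(t.datatype, prefixes)
        base = f'"{escape(str(t))}"'
        if t.lang:
            return f"{base}@{t.lang}"
        from .terms import XSD_STRING

        if t.datatype == XSD_STRING:
            return base
        return f"{base}^^{dt}" if dt else f"{base}^^<{t.datatype}>"
    if isinstance(t, BNode):
        return f"_:{t}"
    c = _curie(str(t), prefixes)
    return c if c is not None else f"<{t}>"


def serialize(g: "_graph.Graph", prefixes: dict[str, str] | None = None) -> str:
    """Deterministic grouped Turtle serialization."""
    prefixes = dict(prefixes or {})
    out = []
    for prefix in sorted(prefixes):
        out.append(f"@prefix {prefix}: <{prefixes[prefix]}> .")
    if prefixes:
        out.append("")

    by_subject: dict = {}
    for s, p, o in g:
        by_subject.setdefault(s, []).append((p, o))

    for s in sorted(by_subject, key=sort_key):
        pairs = by_subject[s]
        by_pred: dict = {}
        for p, o in pairs:
            by_pred.setdefault(p, []).append(o)
        lines = []
        for p in sorted(by_pred, key=sort_key):
            pt = "a" if p == RDF.type else _term_ttl(p, prefixes)
            objs = ", ".join(
                _term_ttl(o, prefixes) for o in sorted(by_pred[p], key=sort_key)
            )
            lines.append(f"    {pt} {objs}")
        out.append(_term_ttl(s, prefixes) + "\n" + " ;\n".join(lines) + " .")
    return "\n".join(out) + "\n"
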