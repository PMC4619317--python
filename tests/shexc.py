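"""A small independent ShExC parser for validating exporter output.

Grammar subset: PREFIX directives; shape declarations
``<iri> { tripleExpr }``; tripleExpr = sequence of constraints/groups
separated by ``;``; group = ``( constraint | constraint ... )`` with an
optional trailing cardinality; constraint = ``<predicate> valueExpr
cardinality?`` where valueExpr is ``@<iri>`` (shape ref), ``<iri>``
(datatype) or ``IRI`` (node kind).  ``#`` comments run to end of line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class Constraint:
    predicate: str
    value_kind: str  # "shape" | "datatype" | "nodekind"
    value: str
    cardinality: str  # "", "?", "+", "*"


@dataclass
class Shape:
    label: str
    constraints: list = field(default_factory=list)  # Constraint or list[Constraint]


_TOKEN = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<ws>\s+)
    | (?P<prefix>PREFIX\s+[A-Za-z_][\w-]*:\s*<[^>]*>)
    | (?P<shaperef>@<[^>]*>)
    | (?P<iri><[^>]*>)
    | (?P<kw>IRI|BNODE|LITERAL|NONLITERAL)
    | (?P<punct>[{}();|])
    | (?P<card>[?+*])
""",
    re.VERBOSE,
)


def _tokens(text: str):
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise SyntaxError(f"ShExC: unexpected input at {text[pos:pos+30]!r}")
        if m.lastgroup not in ("ws", "comment"):
            yield (m.lastgroup, m.group())
        pos = m.end()
    yield ("eof", "")


class _P:
    def __init__(self, text):
        self.toks = list(_tokens(text))
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def next(self):
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise SyntaxError(f"ShExC: expected {value or kind}, got {v!r}")
        return v

    def parse(self):
        shapes = []
        while self.peek()[0] != "eof":
            kind, value = self.peek()
            if kind == "prefix":
                self.next()
                continue
            label = self.expect("iri")[1:-1]
            self.expect("punct", "{")
            constraints = []
            if self.peek() != ("punct", "}"):
                constraints = self.triple_expr()
            self.expect("punct", "}")
            shapes.append(Shape(label, constraints))
        return shapes

    def triple_expr(self):
        items = [self.item()]
        while self.peek() == ("punct", ";"):
            self.next()
            items.append(self.item())
        return items

    def item(self):
        if self.peek() == ("punct", "("):
            self.next()
            group = [self.constraint()]
            while self.peek() == ("punct", "|"):
                self.next()
                group.append(self.constraint())
            self.expect("punct", ")")
            if self.peek()[0] == "card":
                self.next()
            return group
        return self.constraint()

    def constraint(self):
        predicate = self.expect("iri")[1:-1]
        kind, value = self.next()
        if kind == "shaperef":
            vk, val = "shape", value[2:-1]
        elif kind == "iri":
            vk, val = "datatype", value[1:-1]
        elif kind == "kw":
            vk, val = "nodekind", value
        else:
            raise SyntaxError(f"ShExC: bad value expression {value!r}")
        card = ""
        if self.peek()[0] == "card":
            card = self.next()[1]
        return Constraint(predicate, vk, val, card)


def parse_shexc(text: str) -> list[Shape]:
    return _P(text).parse()


def all_constraints(shape: Shape) -> list[Constraint]:
    out = []
    for item in shape.constraints:
        out.extend(item if isinstance(item, list) else [item])
    return out
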