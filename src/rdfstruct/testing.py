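"""A tiny in-process SPARQL endpoint serving one in-memory graph.

This is a test double for backend-equivalence checks: it understands exactly
the query shapes the :class:`~rdfstruct.source.EndpointGraph` backend emits
(ASK {}, the COUNT/type/subClassOf/sameAs/predicate enumerations and
single-predicate statement scans) and answers them in the SPARQL 1.1 JSON
results format.  Serve a pre-skolemized graph if the data contains blank
nodes, so file and endpoint mode agree.
"""

from __future__ import annotations

import json
import re
import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .rdf import Graph, IRI, Literal, BNode, RDF, RDFS, OWL
from .rdf.terms import XSD_STRING

_COUNT_RE = re.compile(r"SELECT \(COUNT\(\*\) AS \?n\) WHERE \{ \?s \?p \?o \}")
_TYPES_RE = re.compile(r"SELECT DISTINCT \?s \?t WHERE \{ \?s a \?t \}")
_PAIR_RE = re.compile(r"SELECT DISTINCT \?x \?y WHERE \{ \?x <([^>]+)> \?y \}")
_PREDS_RE = re.compile(r"SELECT DISTINCT \?p WHERE \{ \?s \?p \?o \}")
_STMTS_RE = re.compile(r"SELECT DISTINCT \?s \?o WHERE \{ \?s <([^>]+)> \?o \}")
_ASK_RE = re.compile(r"ASK\s*\{\s*\}")


def _encode(term) -> dict:
    if isinstance(term, Literal):
        out = {"type": "literal", "value": str(term)}
        if term.lang:
            out["xml:lang"] = term.lang
        elif term.datatype and term.datatype != XSD_STRING:
            out["datatype"] = term.datatype
        return out
    if isinstance(term, BNode):
        return {"type": "bnode", "value": str(term)}
    return {"type": "uri", "value": str(term)}


def evaluate(graph: Graph, query: str) -> dict:
    """Answer one of the supported query shapes over ``graph``."""
    query = " ".join(query.split())
    if _ASK_RE.fullmatch(query):
        return {"head": {}, "boolean": True}
    if _COUNT_RE.fullmatch(query):
        return {
            "head": {"vars": ["n"]},
            "results": {"bindings": [{"n": {
                "type": "literal",
                "datatype": "http://www.w3.org/2001/XMLSchema#integer",
                "value": str(len(graph)),
            }}]},
        }
    if _TYPES_RE.fullmatch(query):
        rows = [
            {"s": _encode(s), "t": _encode(o)}
            for s, _, o in graph.triples(None, RDF.type, None)
        ]
        return {"head": {"vars": ["s", "t"]}, "results": {"bindings": rows}}
    m = _PAIR_RE.fullmatch(query)
    if m:
        rows = [
            {"x": _encode(s), "y": _encode(o)}
            for s, _, o in graph.triples(None, IRI(m.group(1)), None)
        ]
        return {"head": {"vars": ["x", "y"]}, "results": {"bindings": rows}}
    if _PREDS_RE.fullmatch(query):
        rows = [{"p": _encode(p)} for p in sorted({p for _, p, _ in graph})]
        return {"head": {"vars": ["p"]}, "results": {"bindings": rows}}
    m = _STMTS_RE.fullmatch(query)
    if m:
        rows = [
            {"s": _encode(s), "o": _encode(o)}
            for s, _, o in graph.triples(None, IRI(m.group(1)), None)
        ]
        return {"head": {"vars": ["s", "o"]}, "results": {"bindings": rows}}
    raise ValueError(f"unsupported query: {query!r}")


class _Handler(BaseHTTPRequestHandler):
    graph: Graph = Graph()

    def _respond(self, query: str) -> None:
        try:
            payload = evaluate(self.graph, query)
        except ValueError as exc:
            self.send_error(400, str(exc))
            return
        body = json.dumps(payload).encode("utf-8")
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self):  # pragma: no cover - client always POSTs
        params = urllib.parse.parse_qs(urllib.parse.urlparse(self.path).query)
        self._respond(params.get("query", [""])[0])

    def do_POST(self):
        length = int(self.headers.get("Content-Length", "0"))
        params = urllib.parse.parse_qs(self.rfile.read(length).decode("utf-8"))
        self._respond(params.get("query", [""])[0])

    def log_message(self, *args):  # silence request logging
        pass


class LocalEndpoint:
    """Context manager serving a graph on 127.0.0.1:<random port>."""

    def __init__(self, graph: Graph):
        handler = type("Handler", (_Handler,), {"graph": graph})
        self._server = ThreadingHTTPServer(("127.0.0.1", 0), handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        host, port = self._server.server_address
        return f"http://{host}:{port}/sparql"

    def __enter__(self) -> "LocalEndpoint":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()
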