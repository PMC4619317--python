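"""Minimal SPARQL 1.1 protocol client (SELECT/ASK over HTTP, JSON results)."""

from __future__ import annotations

import json
import socket
import urllib.error
import urllib.parse
import urllib.request

from .rdf.terms import IRI, Literal, Term


class EndpointError(ConnectionError):
    """The endpoint could not be reached or answered with an error."""


class QueryTimeout(TimeoutError):
    """A query timed out; carries the predicate being fetched, if any."""

    def __init__(self, message: str, predicate: str | None = None):
        super().__init__(message)
        self.predicate = predicate


def _decode_term(binding: dict) -> Term:
    kind = binding["type"]
    if kind == "uri":
        return IRI(binding["value"])
    if kind in ("literal", "typed-literal"):
        return Literal(
            binding["value"],
            datatype=binding.get("datatype"),
            lang=binding.get("xml:lang"),
        )
    if kind == "bnode":
        # endpoint-side blank nodes are opaque; give them a stable IRI form
        return IRI("urn:bnode:" + binding["value"])
    raise EndpointError(f"unknown term type in SPARQL result: {kind!r}")


class SparqlClient:
    def __init__(self, endpoint: str, timeout: float = 60.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def _request(self, query: str) -> dict:
        data = urllib.parse.urlencode({"query": query}).encode("ascii")
        req = urllib.request.Request(
            self.endpoint,
            data=data,
            headers={
                "Accept": "application/sparql-results+json",
                "Content-Type": "application/x-www-form-urlencoded",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except socket.timeout as exc:
            raise QueryTimeout(f"query timed out after {self.timeout}s") from exc
        except urllib.error.URLError as exc:
            if isinstance(getattr(exc, "reason", None), socket.timeout):
                raise QueryTimeout(f"query timed out after {self.timeout}s") from exc
            raise EndpointError(f"endpoint {self.endpoint} unreachable: {exc}") from exc

    def ask(self, query: str = "ASK {}") -> bool:
        return bool(self._request(query)["boolean"])

    def select(self, query: str) -> list[dict[str, Term]]:
        payload = self._request(query)
        rows = []
        for binding in payload["results"]["bindings"]:
            rows.append({var: _decode_term(term) for var, term in binding.items()})
        return rows
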