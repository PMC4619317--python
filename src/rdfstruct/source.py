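"""Uniform access to the analysed RDF resource.

A :class:`ResourceHandle` names either local RDF files or a SPARQL 1.1
endpoint, plus the IRI prefixes that count as *internal* to the resource.
:func:`load` turns it into a :class:`QueryableGraph` — either backend
answers the same introspection queries with identical, deterministic
(sorted) results, so everything downstream is backend-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .rdf import Graph, IRI, Literal, RDF, RDFS, OWL, SCHEMA_PREDICATES, sort_key
from .sparql import SparqlClient


@dataclass(frozen=True)
class ResourceHandle:
    """Where the resource lives and how to query it."""

    files: tuple[str, ...] = ()
    endpoint: Optional[str] = None
    namespaces: tuple[str, ...] = ()
    limit_per_predicate: Optional[int] = None
    timeout: float = 60.0

    def __post_init__(self):
        if bool(self.files) == bool(self.endpoint):
            raise ValueError("exactly one of files or endpoint must be given")
        if not self.namespaces:
            raise ValueError(
                "at least one internal namespace prefix is required "
                "(needed to distinguish external from invalid objects)"
            )
        if self.limit_per_predicate is not None and self.limit_per_predicate < 1:
            raise ValueError("limit_per_predicate must be >= 1")


class QueryableGraph(Protocol):
    """The introspection contract both backends satisfy."""

    namespaces: tuple[str, ...]

    def n_triples(self) -> int: ...
    def class_instance_counts(self) -> list[tuple[IRI, int]]: ...
    def subclass_links(self) -> list[tuple[IRI, IRI]]: ...
    def predicate_list(self) -> list[IRI]: ...
    def statements(self, predicate: IRI, limit: Optional[int]) -> tuple[list, bool]: ...
    def types_of(self, iri: IRI) -> tuple[IRI, ...]: ...


def _double_sameas(
    subclass_pairs: set[tuple[IRI, IRI]],
    sameas_pairs: set[tuple[IRI, IRI]],
    class_iris: set[IRI],
) -> list[tuple[IRI, IRI]]:
    """Fold sameAs into subClassOf: each class-to-class sameAs pair is
    emitted in both directions."""
    links = set(subclass_pairs)
    for a, b in sameas_pairs:
        if a in class_iris and b in class_iris and a != b:
            links.add((a, b))
            links.add((b, a))
    return sorted(links)


class FileGraph:
    """File-backed QueryableGraph over the in-memory RDF core."""

    def __init__(self, graph: Graph, namespaces: tuple[str, ...]):
        # blank nodes become stable internal IRIs so downstream code only
        # ever sees IRIs and literals
        self._g = graph.skolemize(namespaces[0])
        self.namespaces = namespaces
        self._types: dict[IRI, tuple[IRI, ...]] = {}
        for s, _, o in self._g.triples(None, RDF.type, None):
            if isinstance(o, IRI):
                self._types.setdefault(s, ())
                self._types[s] = tuple(sorted(set(self._types[s]) | {o}))

    def n_triples(self) -> int:
        return len(self._g)

    def class_instance_counts(self) -> list[tuple[IRI, int]]:
        counts: dict[IRI, set] = {}
        for s, _, o in self._g.triples(None, RDF.type, None):
            if isinstance(o, IRI):
                counts.setdefault(o, set()).add(s)
        classes = set(counts)
        for s, _, o in self._g.triples(None, RDFS.subClassOf, None):
            if isinstance(s, IRI):
                classes.add(s)
            if isinstance(o, IRI):
                classes.add(o)
        return [(c, len(counts.get(c, ()))) for c in sorted(classes)]

    def subclass_links(self) -> list[tuple[IRI, IRI]]:
        sub = {
            (s, o)
            for s, _, o in self._g.triples(None, RDFS.subClassOf, None)
            if isinstance(s, IRI) and isinstance(o, IRI)
        }
        same = {
            (s, o)
            for s, _, o in self._g.triples(None, OWL.sameAs, None)
            if isinstance(s, IRI) and isinstance(o, IRI)
        }
        class_iris = {c for c, _ in self.class_instance_counts()}
        return _double_sameas(sub, same, class_iris)

    def predicate_list(self) -> list[IRI]:
        return sorted(
            {p for _, p, _ in self._g if p not in SCHEMA_PREDICATES}
        )

    def statements(self, predicate: IRI, limit: Optional[int] = None):
        pairs = sorted(
            {(s, o) for s, _, o in self._g.triples(None, predicate, None)},
            key=lambda so: (sort_key(so[0]), sort_key(so[1])),
        )
        if limit is not None and len(pairs) > limit:
            return pairs[:limit], True
        return pairs, False

    def types_of(self, iri: IRI) -> tuple[IRI, ...]:
        return self._types.get(iri, ())


class EndpointGraph:
    """SPARQL-endpoint-backed QueryableGraph.

    Result rows are always re-sorted client-side (SPARQL result order is
    unspecified), and ``limit`` truncation takes the sorted prefix, so both
    backends behave identically on the same data.
    """

    def __init__(self, client: SparqlClient, namespaces: tuple[str, ...]):
        self._c = client
        self.namespaces = namespaces
        self._types_cache: Optional[dict[IRI, tuple[IRI, ...]]] = None

    def n_triples(self) -> int:
        rows = self._c.select("SELECT (COUNT(*) AS ?n) WHERE { ?s ?p ?o }")
        return int(str(rows[0]["n"]))

    def _type_map(self) -> dict[IRI, tuple[IRI, ...]]:
        if self._types_cache is None:
            rows = self._c.select("SELECT DISTINCT ?s ?t WHERE { ?s a ?t }")
            tmap: dict[IRI, set] = {}
            for row in rows:
                if isinstance(row["s"], IRI) and isinstance(row["t"], IRI):
                    tmap.setdefault(row["s"], set()).add(row["t"])
            self._types_cache = {s: tuple(sorted(ts)) for s, ts in tmap.items()}
        return self._types_cache

    def class_instance_counts(self) -> list[tuple[IRI, int]]:
        counts: dict[IRI, int] = {}
        for s, ts in self._type_map().items():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        classes = set(counts)
        rows = self._c.select(
            "SELECT DISTINCT ?x ?y WHERE { ?x "
            "<http://www.w3.org/2000/01/rdf-schema#subClassOf> ?y }"
        )
        for row in rows:
            for v in ("x", "y"):
                if isinstance(row[v], IRI):
                    classes.add(row[v])
        return [(c, counts.get(c, 0)) for c in sorted(classes)]

    def subclass_links(self) -> list[tuple[IRI, IRI]]:
        sub_rows = self._c.select(
            "SELECT DISTINCT ?x ?y WHERE { ?x "
            "<http://www.w3.org/2000/01/rdf-schema#subClassOf> ?y }"
        )
        same_rows = self._c.select(
            "SELECT DISTINCT ?x ?y WHERE { ?x "
            "<http://www.w3.org/2002/07/owl#sameAs> ?y }"
        )
        sub = {
            (r["x"], r["y"])
            for r in sub_rows
            if isinstance(r["x"], IRI) and isinstance(r["y"], IRI)
        }
        same = {
            (r["x"], r["y"])
            for r in same_rows
            if isinstance(r["x"], IRI) and isinstance(r["y"], IRI)
        }
        class_iris = {c for c, _ in self.class_instance_counts()}
        return _double_sameas(sub, same, class_iris)

    def predicate_list(self) -> list[IRI]:
        rows = self._c.select("SELECT DISTINCT ?p WHERE { ?s ?p ?o }")
        return sorted(
            {r["p"] for r in rows if r["p"] not in SCHEMA_PREDICATES}
        )

    def statements(self, predicate: IRI, limit: Optional[int] = None):
        from .sparql import QueryTimeout

        try:
            rows = self._c.select(
                "SELECT DISTINCT ?s ?o WHERE { ?s <%s> ?o }" % predicate
            )
        except QueryTimeout as exc:
            raise QueryTimeout(str(exc), predicate=str(predicate)) from exc
        pairs = sorted(
            {(r["s"], r["o"]) for r in rows},
            key=lambda so: (sort_key(so[0]), sort_key(so[1])),
        )
        if limit is not None and len(pairs) > limit:
            return pairs[:limit], True
        return pairs, False

    def types_of(self, iri: IRI) -> tuple[IRI, ...]:
        return self._type_map().get(iri, ())


def load(handle: ResourceHandle) -> QueryableGraph:
    """Open the resource named by ``handle`` for introspection."""
    if handle.endpoint:
        client = SparqlClient(handle.endpoint, timeout=handle.timeout)
        if not client.ask("ASK {}"):  # pragma: no cover - server always true
            raise ConnectionError(f"endpoint {handle.endpoint} rejected ASK {{}}")
        return EndpointGraph(client, handle.namespaces)
    merged = Graph()
    for path in handle.files:
        for s, p, o in Graph.parse_file(path):
            merged.add(s, p, o)
    return FileGraph(merged, handle.namespaces)


# -- spec-level operation aliases -------------------------------------------

def enumerate_classes(g: QueryableGraph) -> list[tuple[IRI, int]]:
    """(class IRI, direct-instance count) pairs, sorted by IRI."""
    return g.class_instance_counts()


def enumerate_subclass_links(g: QueryableGraph) -> list[tuple[IRI, IRI]]:
    """subClassOf pairs with class-to-class sameAs folded in (both directions)."""
    return g.subclass_links()


def enumerate_predicates(g: QueryableGraph) -> list[IRI]:
    """Distinct non-schema predicates, sorted."""
    return g.predicate_list()


def fetch_statements(
    g: QueryableGraph, predicate: IRI, limit: Optional[int] = None
) -> tuple[list, bool]:
    """(subject, object) pairs for a predicate plus a truncation flag."""
    return g.statements(predicate, limit)
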