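"""Domain model of a recovered RDF structure.

The central artifact is :class:`StructureGraph`: the class tree of the
resource, the unique type links observed between class/value types, their
occurrence counts and multiplicities, the per-(class, predicate) grouping
into class properties, and any structural-integrity findings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx

from .rdf.terms import IRI


class ObjectKind(str, enum.Enum):
    """What the object side of a type link refers to."""

    CLASS = "class"
    DATATYPE = "datatype"
    EXTERNAL = "external"
    INVALID = "invalid"

    def __str__(self) -> str:
        return self.value


class Multiplicity(str, enum.Enum):
    ONE_TO_ONE = "1..1"
    ONE_OR_MANY = "1..N"
    ZERO_OR_ONE = "0..1"
    ZERO_OR_MANY = "0..N"
    NOT_DETERMINED = "not determined"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_bounds(cls, lower: int, upper: str) -> "Multiplicity":
        return cls(f"{lower}..{upper}")

    @property
    def bounds(self) -> tuple[int, str]:
        lower, upper = self.value.split("..")
        return int(lower), upper


def classify_forward(total_instances: int, refcounts: Iterable[int]) -> Multiplicity:
    """Coarse cardinality of a link from per-subject distinct-object counts.

    ``total_instances`` is the number of instances of the subject class;
    ``refcounts`` holds, per subject actually participating in the link,
    the number of distinct objects it references.
    """
    counts = list(refcounts)
    participating = len(counts)
    if participating == 0:
        raise ValueError("a type link without participating subjects cannot exist")
    if any(c < 1 for c in counts):
        raise ValueError("refcounts must all be >= 1")
    if participating > total_instances:
        raise ValueError("more participating subjects than instances")
    lower = 1 if participating == total_instances else 0
    upper = "1" if max(counts) == 1 else "N"
    return Multiplicity.from_bounds(lower, upper)


def aggregate_multiplicity(ms: Iterable[Multiplicity]) -> Multiplicity:
    """Conservative widening of multiplicities of merged links.

    ``not determined`` is absorbing; otherwise the lower bound drops to 0 and
    the upper bound rises to N as soon as any constituent says so.
    """
    ms = list(ms)
    if not ms:
        raise ValueError("cannot aggregate zero multiplicities")
    if any(m is Multiplicity.NOT_DETERMINED for m in ms):
        return Multiplicity.NOT_DETERMINED
    lower = min(m.bounds[0] for m in ms)
    upper = "N" if any(m.bounds[1] == "N" for m in ms) else "1"
    return Multiplicity.from_bounds(lower, upper)


@dataclass(frozen=True, order=True)
class TypeLink:
    """One observed (subject type, predicate, object type) combination."""

    subject_type: IRI
    predicate: IRI
    object_type: IRI
    object_kind: ObjectKind


@dataclass(frozen=True, order=True)
class UniqueTypeLink:
    """A deduplicated type link with occurrence count and multiplicities."""

    subject_type: IRI
    predicate: IRI
    object_type: IRI
    object_kind: ObjectKind
    count: int = 1
    forward: Multiplicity = Multiplicity.NOT_DETERMINED
    reverse: Multiplicity = Multiplicity.NOT_DETERMINED

    @property
    def key(self) -> TypeLink:
        return TypeLink(self.subject_type, self.predicate, self.object_type, self.object_kind)


class ClassTree:
    """Directed class hierarchy (child -> parent edges) with instance counts.

    ``sameAs`` pairs arrive as two opposite subClassOf edges, so cycles are
    legal; every strongly connected component is treated as one equivalence
    group whose representative is its lexicographically smallest IRI.
    """

    def __init__(self):
        self._g = nx.DiGraph()
        self._condensed: Optional[nx.DiGraph] = None
        self._rep: dict[IRI, IRI] = {}
        self.concepts: set[IRI] = set()

    # -- construction ---------------------------------------------------
    def add_class(self, iri: IRI, instance_count: int = 0) -> None:
        if iri in self._g.nodes:
            self._g.nodes[iri]["count"] = instance_count
        else:
            self._g.add_node(iri, count=instance_count)
        self._condensed = None

    def add_edge(self, child: IRI, parent: IRI) -> None:
        for n in (child, parent):
            if n not in self._g.nodes:
                self._g.add_node(n, count=0)
        self._g.add_edge(child, parent)
        self._condensed = None

    # -- accessors --------------------------------------------------------
    @property
    def classes(self) -> list[IRI]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[IRI, IRI]]:
        return sorted(self._g.edges)

    def __contains__(self, iri: IRI) -> bool:
        return iri in self._g.nodes

    def instance_count(self, iri: IRI) -> int:
        return self._g.nodes[iri]["count"]

    def is_concept(self, iri: IRI) -> bool:
        return iri in self.concepts

    def direct_parents(self, iri: IRI) -> list[IRI]:
        return sorted(self._g.successors(iri))

    def direct_children(self, iri: IRI) -> list[IRI]:
        return sorted(self._g.predecessors(iri))

    # -- equivalence groups / condensation -------------------------------
    def _condense(self) -> nx.DiGraph:
        if self._condensed is None:
            comp = list(nx.strongly_connected_components(self._g))
            self._rep = {}
            dag = nx.DiGraph()
            for group in comp:
                rep = min(group)
                dag.add_node(rep, members=frozenset(group))
                for node in group:
                    self._rep[node] = rep
            for u, v in self._g.edges:
                ru, rv = self._rep[u], self._rep[v]
                if ru != rv:
                    dag.add_edge(ru, rv)
            self._condensed = dag
        return self._condensed

    def rep(self, iri: IRI) -> IRI:
        """Equivalence-group representative (lexicographically smallest)."""
        self._condense()
        return self._rep.get(iri, iri)

    def group(self, iri: IRI) -> frozenset:
        dag = self._condense()
        return dag.nodes[self.rep(iri)]["members"]

    def group_reps(self) -> list[IRI]:
        return sorted(self._condense().nodes)

    def group_parents(self, iri: IRI) -> list[IRI]:
        """Representatives of the direct parent groups."""
        return sorted(self._condense().successors(self.rep(iri)))

    def group_children(self, iri: IRI) -> list[IRI]:
        return sorted(self._condense().predecessors(self.rep(iri)))

    # -- hierarchy queries ------------------------------------------------
    def child_of(self, k: IRI, l: IRI) -> bool:
        """True iff class k equals l or is a (transitive) subclass of l."""
        rk, rl = self.rep(k), self.rep(l)
        if rk == rl:
            return True
        dag = self._condense()
        if rk not in dag.nodes or rl not in dag.nodes:
            return False
        return nx.has_path(dag, rk, rl)

    def ancestors(self, iri: IRI) -> list[IRI]:
        """Proper ancestors (group representatives), sorted."""
        dag = self._condense()
        rep = self.rep(iri)
        if rep not in dag.nodes:
            return []
        return sorted(nx.descendants(dag, rep))

    def descendants(self, iri: IRI) -> list[IRI]:
        dag = self._condense()
        rep = self.rep(iri)
        if rep not in dag.nodes:
            return []
        return sorted(nx.ancestors(dag, rep))

    def up_distance(self, child: IRI, ancestor: IRI) -> Optional[int]:
        """Shortest upward distance from child's group to ancestor's, or None."""
        rc, ra = self.rep(child), self.rep(ancestor)
        if rc == ra:
            return 0
        dag = self._condense()
        try:
            return nx.shortest_path_length(dag, rc, ra)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None

    def nearest_common_ancestor(self, a: IRI, b: IRI) -> Optional[IRI]:
        """Common ancestor minimizing the larger of the two distances;
        ties broken lexicographically. Includes a/b themselves."""
        ra, rb = self.rep(a), self.rep(b)
        cand_a = {ra} | set(self.ancestors(ra))
        cand_b = {rb} | set(self.ancestors(rb))
        common = cand_a & cand_b
        if not common:
            return None
        return min(
            common,
            key=lambda c: (max(self.up_distance(ra, c), self.up_distance(rb, c)), c),
        )

    def group_instance_count(self, iri: IRI) -> int:
        return sum(self._g.nodes[m]["count"] for m in self.group(iri))

    def roots(self) -> list[IRI]:
        dag = self._condense()
        return sorted(n for n in dag.nodes if dag.out_degree(n) == 0)

    # -- equality (used by the structure-RDF round trip) -----------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, ClassTree):
            return NotImplemented
        return (
            {n: self._g.nodes[n]["count"] for n in self._g.nodes}
            == {n: other._g.nodes[n]["count"] for n in other._g.nodes}
            and set(self._g.edges) == set(other._g.edges)
            and self.concepts == other.concepts
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClassTree({self._g.number_of_nodes()} classes, {self._g.number_of_edges()} edges)"


@dataclass(frozen=True)
class ClassProperty:
    """All unique type links of one class for one predicate."""

    owner_class: IRI
    predicate: IRI
    links: tuple[UniqueTypeLink, ...]

    @property
    def occurrences(self) -> int:
        return sum(l.count for l in self.links)


class FindingKind(str, enum.Enum):
    UNDETERMINED_MULTIPLICITY = "undetermined_multiplicity"
    UNTYPED_SUBJECT_WITH_PROPERTIES = "untyped_subject_with_properties"
    PREDICATE_ALSO_CLASS = "predicate_also_class"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=True)
class IntegrityFinding:
    kind: FindingKind
    subject: str
    detail: str


@dataclass
class StructureGraph:
    """The whole recovered structure; the unit all exporters consume.

    ``findings`` are re-derivable from the source and are excluded from
    equality (the structure-RDF round trip does not serialize them).
    """

    class_tree: ClassTree
    links: tuple[UniqueTypeLink, ...]
    findings: tuple[IntegrityFinding, ...] = field(default=(), compare=False)
    truncated_predicates: frozenset = field(default_factory=frozenset, compare=False)

    @property
    def class_properties(self) -> tuple[ClassProperty, ...]:
        groups: dict[tuple[IRI, IRI], list[UniqueTypeLink]] = {}
        for link in sorted(self.links):
            groups.setdefault((link.subject_type, link.predicate), []).append(link)
        return tuple(
            ClassProperty(owner, pred, tuple(ls))
            for (owner, pred), ls in sorted(groups.items())
        )

    @property
    def predicates(self) -> list[IRI]:
        return sorted({l.predicate for l in self.links})

    def links_for(self, predicate: IRI) -> tuple[UniqueTypeLink, ...]:
        return tuple(l for l in sorted(self.links) if l.predicate == predicate)

    def multiplicity_histogram(self) -> dict[str, int]:
        hist = {str(m): 0 for m in Multiplicity}
        for l in self.links:
            hist[str(l.forward)] += 1
        return hist

    def replace(self, **kw) -> "StructureGraph":
        return replace(self, **kw)
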