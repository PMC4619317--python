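"""Programmatic generation of RDF test graphs with known structure.

:func:`generate` builds a Turtle graph from a :class:`FixtureSpec` *and*
the ground-truth :class:`StructureGraph` it realizes, so recovery can be
tested exactly.  The ground truth is computed from the generator's own
statement records by elementary counting — construction is the oracle, the
graph is never re-parsed.

:func:`paper_examples` provides the small hand-written graphs used
throughout the documentation and the acceptance tests: the gene/chromosome
and person/son graphs, the three hierarchy-merge cases, and a graph where
one IRI is used both as a class and as a predicate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    ClassTree,
    FindingKind,
    IntegrityFinding,
    Multiplicity,
    ObjectKind,
    StructureGraph,
    TypeLink,
    UniqueTypeLink,
)
from .rdf import Graph, IRI, Literal, RDF, RDFS, XSD, sort_key

NS = "http://example.org/fx/"
EXTERNAL_NS = "http://external.example/"


@dataclass(frozen=True)
class PredicateSpec:
    """One predicate to realize, with its intended forward multiplicity."""

    name: str
    target_kind: ObjectKind = ObjectKind.CLASS
    forward: Multiplicity = Multiplicity.ONE_TO_ONE
    source_class: str = ""  # local class name; "" = root
    target_class: str = ""  # local class name (class targets); "" = root


@dataclass(frozen=True)
class FixtureSpec:
    tree_depth: int = 1
    branching: int = 2
    instances_per_class: int | tuple[int, int] = 3
    predicates: tuple[PredicateSpec, ...] = ()
    fraction_untyped: float = 0.0
    fraction_external: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.tree_depth < 1 or self.branching < 1:
            raise ValueError("tree_depth and branching must be >= 1")
        for frac in (self.fraction_untyped, self.fraction_external):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be within [0, 1]")


def _class_names(depth: int, branching: int) -> tuple[list[str], list[tuple[str, str]]]:
    names, edges = ["C"], []
    frontier = ["C"]
    for _ in range(depth - 1):
        nxt = []
        for parent in frontier:
            for b in range(branching):
                child = f"{parent}{b}"
                names.append(child)
                edges.append((child, parent))
                nxt.append(child)
        frontier = nxt
    return names, edges


def _classify(o, type_map: dict) -> tuple[IRI, ObjectKind]:
    if isinstance(o, Literal):
        return IRI(o.datatype), ObjectKind.DATATYPE
    if o in type_map:
        return type_map[o], ObjectKind.CLASS
    if str(o).startswith(NS):
        return IRI(NS), ObjectKind.INVALID
    return IRI(o.namespace()), ObjectKind.EXTERNAL


def _bounds(total: int, per_subject: dict) -> Multiplicity:
    lower = 1 if len(per_subject) == total else 0
    upper = "1" if max(len(v) for v in per_subject.values()) == 1 else "N"
    return Multiplicity(f"{lower}..{upper}")


def generate(spec: FixtureSpec) -> tuple[str, StructureGraph]:
    """Emit (Turtle text, ground-truth structure) for a fixture spec."""
    rng = random.Random(spec.seed)
    names, edges = _class_names(spec.tree_depth, spec.branching)
    classes = {name: IRI(NS + name) for name in names}

    # instances, each directly typed with exactly one class
    instances: dict[str, list[IRI]] = {}
    type_map: dict[IRI, IRI] = {}
    for name in names:
        if isinstance(spec.instances_per_class, tuple):
            n = rng.randint(*spec.instances_per_class)
        else:
            n = spec.instances_per_class
        instances[name] = [IRI(f"{NS}i/{name}_{k}") for k in range(n)]
        for inst in instances[name]:
            type_map[inst] = classes[name]

    statements: list[tuple[IRI, IRI, object]] = []
    orphan_n = external_n = literal_n = 0
    orphans: list[IRI] = []

    def fresh_orphan() -> IRI:
        nonlocal orphan_n
        orphan_n += 1
        node = IRI(f"{NS}orphan{orphan_n}")
        orphans.append(node)
        return node

    def fresh_external() -> IRI:
        nonlocal external_n
        external_n += 1
        return IRI(f"{EXTERNAL_NS}res/{external_n}")

    def fresh_literal() -> Literal:
        nonlocal literal_n
        literal_n += 1
        return Literal(f"value {literal_n}")

    for ps in spec.predicates:
        pred = IRI(NS + ps.name)
        source = ps.source_class or "C"
        subjects = instances[source]
        if not subjects:
            raise ValueError(f"source class {source} has no instances")
        lower, upper = ps.forward.bounds
        participating = list(subjects)
        if lower == 0:
            if len(subjects) < 2:
                raise ValueError("0..* multiplicities need >= 2 source instances")
            participating = subjects[: -max(1, len(subjects) // 3)]
        target_pool: list = []
        if ps.target_kind is ObjectKind.CLASS:
            target_pool = list(instances[ps.target_class or "C"])
            if not target_pool:
                raise ValueError("class-target predicate needs target instances")
        for si, subj in enumerate(participating):
            n_refs = 1
            if upper == "N":
                n_refs = 2 if si == 0 else rng.randint(1, 2)
            seen: set = set()
            for r in range(n_refs):
                roll = rng.random()
                if ps.target_kind is ObjectKind.CLASS and roll < spec.fraction_untyped:
                    obj = fresh_orphan()
                elif (
                    ps.target_kind is ObjectKind.CLASS
                    and roll < spec.fraction_untyped + spec.fraction_external
                ):
                    obj = fresh_external()
                elif ps.target_kind is ObjectKind.CLASS:
                    obj = target_pool[(si + r) % len(target_pool)]
                    if obj in seen:  # guarantee distinct objects per subject
                        obj = target_pool[(si + r + 1) % len(target_pool)]
                elif ps.target_kind is ObjectKind.DATATYPE:
                    obj = fresh_literal()
                elif ps.target_kind is ObjectKind.EXTERNAL:
                    obj = fresh_external()
                else:
                    obj = fresh_orphan()
                if obj in seen:
                    continue
                seen.add(obj)
                statements.append((subj, pred, obj))

    # every orphan bears a property, making it an untyped subject with
    # properties (the corresponding integrity finding)
    note = IRI(NS + "note")
    for orphan in orphans:
        statements.append((orphan, note, Literal(f"orphan {orphan}")))

    # ---- serialize ---------------------------------------------------
    g = Graph()
    for child, parent in edges:
        g.add(classes[child], RDFS.subClassOf, classes[parent])
    for inst, cls in type_map.items():
        g.add(inst, RDF.type, cls)
    for s, p, o in statements:
        g.add(s, p, o)
    turtle = g.serialize("turtle", prefixes={"fx": NS, "xsd": str(XSD)})

    # ---- ground truth -------------------------------------------------
    tree = ClassTree()
    for name in names:
        tree.add_class(classes[name], len(instances[name]))
    for child, parent in edges:
        tree.add_edge(classes[child], classes[parent])
    # concept flags by brute-force descendant scan
    down: dict[str, set[str]] = {name: {name} for name in names}
    for _ in names:
        for child, parent in edges:
            down[parent] |= down[child]
    tree.concepts = {
        classes[name]
        for name in names
        if all(not instances[d] for d in down[name])
    }

    registries: dict[TypeLink, set] = {}
    untyped_subjects: set[IRI] = set()
    for s, p, o in statements:
        if s not in type_map:
            untyped_subjects.add(s)
            continue
        ot, kind = _classify(o, type_map)
        key = TypeLink(type_map[s], p, ot, kind)
        registries.setdefault(key, set()).add((s, o))

    class_totals = {classes[name]: len(instances[name]) for name in names}
    links = []
    for key in sorted(registries):
        registry = registries[key]
        if key.object_kind is ObjectKind.INVALID:
            fwd = rev = Multiplicity.NOT_DETERMINED
        else:
            per_subject: dict = {}
            for s, o in registry:
                per_subject.setdefault(s, set()).add(o)
            fwd = _bounds(class_totals[key.subject_type], per_subject)
            if key.object_kind is ObjectKind.CLASS:
                per_object: dict = {}
                for s, o in registry:
                    per_object.setdefault(o, set()).add(s)
                rev = _bounds(class_totals[key.object_type], per_object)
            else:
                rev = Multiplicity.NOT_DETERMINED
        links.append(
            UniqueTypeLink(
                key.subject_type, key.predicate, key.object_type, key.object_kind,
                count=len(registry), forward=fwd, reverse=rev,
            )
        )

    findings = []
    for link in sorted(links):
        if link.object_kind is ObjectKind.INVALID:
            findings.append(
                IntegrityFinding(
                    FindingKind.UNDETERMINED_MULTIPLICITY,
                    f"{link.subject_type} --{link.predicate}--> {link.object_type}",
                    "multiplicity not determined: link references invalid "
                    "(untyped, in-namespace) subjects",
                )
            )
    for subject in sorted(untyped_subjects, key=sort_key):
        findings.append(
            IntegrityFinding(
                FindingKind.UNTYPED_SUBJECT_WITH_PROPERTIES,
                str(subject),
                "subject has properties but no rdf:type declaration",
            )
        )

    structure = StructureGraph(
        class_tree=tree, links=tuple(sorted(links)), findings=tuple(sorted(findings))
    )
    return turtle, structure


# ---------------------------------------------------------------------------
# hand-written example graphs


@dataclass(frozen=True)
class Example:
    name: str
    turtle: str
    namespaces: tuple[str, ...] = ("http://example.org/",)


_GENE_CHROMOSOME = """
@prefix : <http://example.org/> .
:chr1 a :Chromosome . :chr2 a :Chromosome .
""" + "\n".join(
    f":gene{i} a :Gene ; :locatedOn :chr{(i % 2) + 1} ." for i in range(1, 11)
)

_PERSON_HASSON = """
@prefix : <http://example.org/> .
:Adam a :Person ; :hasSon :Bob, :Ben .
:Eve a :Person ; :hasSon :Bob, :Ben .
:Carl a :Person .
:Bob a :Person .
:Ben a :Person .
"""

_FIG2_A = """
@prefix : <http://example.org/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:Y1 rdfs:subClassOf :Y . :Y2 rdfs:subClassOf :Y .
:x1 a :X ; :p :y1 .
:x2 a :X ; :p :y2 .
:y1 a :Y1 . :y2 a :Y2 .
"""

_FIG2_B = """
@prefix : <http://example.org/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:X1 rdfs:subClassOf :X . :X2 rdfs:subClassOf :X .
:x11 a :X1 ; :p :y1 .
:x21 a :X2 ; :p :y2 .
:y1 a :Y . :y2 a :Y .
"""

_FIG2_C = """
@prefix : <http://example.org/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:X1 rdfs:subClassOf :X . :X2 rdfs:subClassOf :X .
:Y1 rdfs:subClassOf :Y . :Y2 rdfs:subClassOf :Y .
:x11 a :X1 ; :p :y11 .
:x21 a :X2 ; :p :y21 .
:y11 a :Y1 . :y21 a :Y2 .
"""

_CDS_COLLISION = """
@prefix : <http://example.org/> .
:c1 a :CDS .
:g1 a :Gene ; :CDS :c1 .
"""


def paper_examples() -> dict[str, Example]:
    """The named example graphs used by documentation and acceptance tests."""
    return {
        "gene_chromosome": Example("gene_chromosome", _GENE_CHROMOSOME),
        "person_hasson": Example("person_hasson", _PERSON_HASSON),
        "fig2_case_a": Example("fig2_case_a", _FIG2_A),
        "fig2_case_b": Example("fig2_case_b", _FIG2_B),
        "fig2_case_c": Example("fig2_case_c", _FIG2_C),
        "cds_collision": Example("cds_collision", _CDS_COLLISION),
    }
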