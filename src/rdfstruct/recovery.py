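"""Recovery of the raw structure: class tree, type links, unique type links
with occurrence counts and forward/reverse multiplicities, concept classes.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    ClassTree,
    FindingKind,
    IntegrityFinding,
    Multiplicity,
    ObjectKind,
    StructureGraph,
    TypeLink,
    UniqueTypeLink,
    classify_forward,
)
from .rdf import IRI, Literal, sort_key
from .source import (
    QueryableGraph,
    ResourceHandle,
    enumerate_classes,
    enumerate_predicates,
    enumerate_subclass_links,
    fetch_statements,
    load,
)


def build_class_tree(classes, subclass_links) -> ClassTree:
    tree = ClassTree()
    for iri, count in classes:
        tree.add_class(iri, count)
    for child, parent in subclass_links:
        tree.add_edge(child, parent)
    return tree


def detect_concept_classes(tree: ClassTree) -> ClassTree:
    """Flag classes with no instances anywhere below them (inclusive)."""
    tree.concepts = {
        c
        for c in tree.classes
        if tree.instance_count(c) == 0
        and all(
            tree.instance_count(m) == 0
            for d in tree.descendants(c)
            for m in tree.group(d)
        )
        and all(tree.instance_count(m) == 0 for m in tree.group(c))
    }
    return tree


def classify_object(
    term, g: QueryableGraph, namespaces
) -> tuple[tuple[IRI, ObjectKind], ...]:
    """All (object type, kind) classifications of one object term.

    Literals map to their datatype; typed IRIs yield one classification per
    declared class; untyped IRIs are *invalid* when inside one of the
    resource's namespaces and *external* otherwise (typed by their
    host-level namespace prefix).
    """
    if isinstance(term, Literal):
        return ((IRI(term.datatype), ObjectKind.DATATYPE),)
    types = g.types_of(term)
    if types:
        return tuple((t, ObjectKind.CLASS) for t in types)
    for ns in namespaces:
        if str(term).startswith(ns):
            return ((IRI(ns), ObjectKind.INVALID),)
    return ((IRI(term.namespace()), ObjectKind.EXTERNAL),)


def extract_type_links(
    g: QueryableGraph, class_tree: ClassTree, handle: ResourceHandle
) -> tuple[dict[TypeLink, set], set[IRI], set[IRI]]:
    """Scan all non-schema statements.

    Returns (registries, untyped_subjects, truncated_predicates) where
    ``registries`` maps each unique type-link tuple to its contributing
    (subject, object) statement pairs.
    """
    registries: dict[TypeLink, set] = {}
    untyped_subjects: set[IRI] = set()
    truncated: set[IRI] = set()
    for predicate in enumerate_predicates(g):
        pairs, was_truncated = fetch_statements(g, predicate, handle.limit_per_predicate)
        if was_truncated:
            truncated.add(predicate)
        for s, o in pairs:
            subject_types = g.types_of(s) if isinstance(s, IRI) else ()
            if not subject_types:
                untyped_subjects.add(s)
                continue
            for st in subject_types:
                for ot, kind in classify_object(o, g, handle.namespaces):
                    key = TypeLink(st, predicate, ot, kind)
                    registries.setdefault(key, set()).add((s, o))
    return registries, untyped_subjects, truncated


def classify_reverse(
    link: TypeLink, registry: set, class_tree: ClassTree
) -> Multiplicity:
    """Multiplicity with source and target roles inverted; only class
    targets have an instance total, anything else is not determined."""
    if link.object_kind is not ObjectKind.CLASS:
        return Multiplicity.NOT_DETERMINED
    total = class_tree.instance_count(link.object_type)
    per_object: dict = {}
    for s, o in registry:
        per_object.setdefault(o, set()).add(s)
    return classify_forward(total, [len(v) for v in per_object.values()])


def _link_from_registry(
    key: TypeLink, registry: set, class_tree: ClassTree, truncated: set[IRI]
) -> UniqueTypeLink:
    count = len(registry)
    if key.predicate in truncated or key.object_kind is ObjectKind.INVALID:
        fwd = rev = Multiplicity.NOT_DETERMINED
    else:
        per_subject: dict = {}
        for s, o in registry:
            per_subject.setdefault(s, set()).add(o)
        total = class_tree.instance_count(key.subject_type)
        fwd = classify_forward(total, [len(v) for v in per_subject.values()])
        rev = classify_reverse(key, registry, class_tree)
    return UniqueTypeLink(
        key.subject_type, key.predicate, key.object_type, key.object_kind,
        count=count, forward=fwd, reverse=rev,
    )


def derive_findings(
    links, untyped_subjects, predicates, class_iris
) -> tuple[IntegrityFinding, ...]:
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
    for iri in sorted(set(predicates) & set(class_iris)):
        findings.append(
            IntegrityFinding(
                FindingKind.PREDICATE_ALSO_CLASS,
                str(iri),
                "IRI is used both as a class and as a predicate",
            )
        )
    return tuple(sorted(findings))


def recover_from_graph(g: QueryableGraph, handle: ResourceHandle) -> StructureGraph:
    classes = enumerate_classes(g)
    tree = build_class_tree(classes, enumerate_subclass_links(g))
    tree = detect_concept_classes(tree)

    registries, untyped_subjects, truncated = extract_type_links(g, tree, handle)
    links = tuple(
        _link_from_registry(key, registries[key], tree, truncated)
        for key in sorted(registries)
    )
    findings = derive_findings(
        links, untyped_subjects, enumerate_predicates(g), [c for c, _ in classes]
    )
    return StructureGraph(
        class_tree=tree,
        links=links,
        findings=findings,
        truncated_predicates=frozenset(truncated),
    )


def recover(handle: ResourceHandle) -> StructureGraph:
    """Full recovery pipeline: load the resource and build its structure."""
    return recover_from_graph(load(handle), handle)
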