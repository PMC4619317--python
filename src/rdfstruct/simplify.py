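"""Per-predicate merging of unique type links over the class hierarchy.

For each predicate the merge runs five phases:

1. seed one temporary link per unique type link, at the subject class;
2. copy every temporary link to all ancestor classes, then repeatedly merge
   pairs (two at a time, in sorted order) on the same class whose targets
   are *shared*, replacing them by one link to the common ancestor type;
3. breadth-first from the roots, drop a purely-inherited temporary link when
   exactly one direct child already owns a covering link;
4. top-down, drop any temporary link whose target is covered by a link on an
   ancestor class;
5. attribute every original link to exactly one survivor and emit survivors
   as unique type links (counts summed, multiplicities widened).

Phase 3 never drops a link seeded at the class itself: instances of that
very class use the predicate, so pushing the link down to the single child
would lose coverage.  Phase 5's unique attribution keeps the per-predicate
counts an exact partition of the original counts even under multiple
inheritance.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    ClassTree,
    Multiplicity,
    ObjectKind,
    StructureGraph,
    UniqueTypeLink,
    aggregate_multiplicity,
)
from .rdf.terms import IRI


def child_of(k: IRI, l: IRI, tree: ClassTree) -> bool:
    """True iff class k equals l or is a (transitive) subclass of l."""
    return tree.child_of(k, l)


def shared(
    t1: tuple[IRI, ObjectKind], t2: tuple[IRI, ObjectKind], tree: ClassTree
) -> Optional[tuple[IRI, ObjectKind]]:
    """The type two targets merge into, or None.

    Identical targets share trivially; class targets additionally share when
    one is an ancestor of the other or both have a common ancestor (the
    nearest one, ties broken lexicographically).  Non-class targets only
    share when identical.
    """
    (i1, k1), (i2, k2) = t1, t2
    if k1 != k2:
        return None
    if k1 is not ObjectKind.CLASS:
        return t1 if i1 == i2 else None
    if tree.rep(i1) == tree.rep(i2):
        return (min(tree.group(i1)), k1)
    nca = tree.nearest_common_ancestor(i1, i2)
    if nca is None:
        return None
    return (nca, ObjectKind.CLASS)


def _covers(target: tuple, other: tuple, tree: ClassTree) -> bool:
    """Does ``other`` fall under ``target`` (equal, or subclass for classes)?"""
    (ti, tk), (oi, ok) = target, other
    if tk != ok:
        return False
    if tk is ObjectKind.CLASS:
        return tree.child_of(oi, ti)
    return ti == oi


@dataclass
class TempLink:
    """Working link during the merge of one predicate."""

    target: tuple  # (IRI, ObjectKind)
    provenance: frozenset  # indices into the original link list
    seeded_here: bool = False

    def sort_token(self) -> tuple:
        return (self.target[1].value, str(self.target[0]), sorted(self.provenance))


def _merge_round(links: list[TempLink], tree: ClassTree) -> bool:
    """Merge the first shared pair (sorted order); True if anything merged."""
    links.sort(key=TempLink.sort_token)
    for i in range(len(links)):
        for j in range(i + 1, len(links)):
            t = shared(links[i].target, links[j].target, tree)
            if t is None:
                continue
            merged = TempLink(
                target=t,
                provenance=links[i].provenance | links[j].provenance,
                seeded_here=links[i].seeded_here or links[j].seeded_here,
            )
            del links[j]
            del links[i]
            links.append(merged)
            return True
    return False


def simplify_predicate(
    links: Sequence[UniqueTypeLink], tree: ClassTree
) -> tuple[UniqueTypeLink, ...]:
    """Run the five merge phases for the links of one predicate."""
    if not links:
        return ()
    predicate = links[0].predicate
    if any(l.predicate != predicate for l in links):
        raise ValueError("simplify_predicate expects links of a single predicate")

    originals = sorted(links)
    # phase 1: seed
    state: dict[IRI, list[TempLink]] = {}
    for idx, link in enumerate(originals):
        cls = tree.rep(link.subject_type)
        state.setdefault(cls, []).append(
            TempLink(
                target=(link.object_type, link.object_kind),
                provenance=frozenset([idx]),
                seeded_here=True,
            )
        )

    # phase 2: copy every link to all (transitive) ancestors once, then merge
    # shared pairs per class until fixpoint.  Ancestors receive copies of all
    # constituents, so they reach their own merge fixpoint without re-copying.
    for cls in sorted(state):
        for ancestor in tree.ancestors(cls):
            dest = state.setdefault(ancestor, [])
            present = {(t.target, t.provenance) for t in dest}
            for t in list(state[cls]):
                if (t.target, t.provenance) not in present:
                    dest.append(TempLink(t.target, t.provenance, seeded_here=False))
                    present.add((t.target, t.provenance))
    for cls in sorted(state):
        while _merge_round(state[cls], tree):
            pass

    # make sure seeded flags survived merging of copies with seeds
    for cls, temp_links in state.items():
        for t in temp_links:
            if any(tree.rep(originals[i].subject_type) == cls for i in t.provenance):
                t.seeded_here = True

    # phase 3: breadth-first from roots; drop inherited links that exactly
    # one direct child already covers
    order: list[IRI] = []
    depth: dict[IRI, int] = {}
    queue = deque()
    for root in tree.roots():
        depth[root] = 0
        queue.append(root)
    seen = set()
    while queue:
        cls = queue.popleft()
        if cls in seen:
            continue
        seen.add(cls)
        order.append(cls)
        for child in tree.group_children(cls):
            if child not in seen:
                depth.setdefault(child, depth[cls] + 1)
                queue.append(child)
    order.sort(key=lambda c: (depth.get(c, 0), c))
    for cls in order:
        for t in list(state.get(cls, ())):
            if t.seeded_here:
                continue
            covering_children = sum(
                1
                for child in tree.group_children(cls)
                if any(_covers(t.target, u.target, tree) for u in state.get(child, ()))
            )
            if covering_children == 1:
                state[cls].remove(t)

    # phase 4: top-down, drop links covered by a surviving ancestor link
    for cls in order:
        for t in list(state.get(cls, ())):
            if any(
                _covers(u.target, t.target, tree)
                for ancestor in tree.ancestors(cls)
                for u in state.get(ancestor, ())
            ):
                state[cls].remove(t)

    # phase 5: attribute each original to its best (nearest, then
    # lexicographically smallest) surviving link and emit
    survivors = [
        (cls, t) for cls in sorted(state) for t in sorted(state[cls], key=TempLink.sort_token)
    ]
    assignment: dict[int, int] = {}
    for idx, link in enumerate(originals):
        best = None
        for si, (cls, t) in enumerate(survivors):
            if not tree.child_of(link.subject_type, cls):
                continue
            if not _covers(t.target, (link.object_type, link.object_kind), tree):
                continue
            d_subj = tree.up_distance(link.subject_type, cls) or 0
            d_targ = (
                tree.up_distance(link.object_type, t.target[0]) or 0
                if link.object_kind is ObjectKind.CLASS
                else 0
            )
            score = (d_subj + d_targ, str(cls), str(t.target[0]))
            if best is None or score < best[0]:
                best = (score, si)
        if best is None:  # pragma: no cover - phases 3/4 preserve coverage
            raise AssertionError(f"original link lost during simplification: {link}")
        assignment[idx] = best[1]

    out = []
    for si, (cls, t) in enumerate(survivors):
        members = [originals[i] for i, s in sorted(assignment.items()) if s == si]
        if not members:
            continue  # fully redundant copy; its originals live elsewhere
        out.append(
            UniqueTypeLink(
                subject_type=cls,
                predicate=predicate,
                object_type=t.target[0],
                object_kind=t.target[1],
                count=sum(m.count for m in members),
                forward=aggregate_multiplicity([m.forward for m in members]),
                reverse=aggregate_multiplicity([m.reverse for m in members]),
            )
        )
    return tuple(sorted(out))


def simplify(structure: StructureGraph) -> StructureGraph:
    """Apply the per-predicate merge to every predicate, in sorted order."""
    merged: list[UniqueTypeLink] = []
    for predicate in structure.predicates:
        merged.extend(simplify_predicate(structure.links_for(predicate), structure.class_tree))
    return structure.replace(links=tuple(sorted(merged)))
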