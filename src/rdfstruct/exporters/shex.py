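"""ShEx compact syntax (ShExC, ShEx 2.x) export.

One shape per class with instances; one triple constraint per class
property, with the links of a multi-link property emitted as a OneOf group.
Forward multiplicity maps onto ShExC cardinality as: 1..1 -> (none),
0..1 -> ``?``, 1..N -> ``+``, 0..N -> ``*``; a link whose multiplicity
could not be determined is emitted permissively as ``*`` with a warning
comment.  Datatype targets become literal datatype constraints, class
targets shape references, and external/invalid targets IRI node-kind
constraints annotated with their kind.
"""

from __future__ import annotations

from ..model import Multiplicity, ObjectKind, StructureGraph, UniqueTypeLink

_CARDINALITY = {
    Multiplicity.ONE_TO_ONE: "",
    Multiplicity.ZERO_OR_ONE: "?",
    Multiplicity.ONE_OR_MANY: "+",
    Multiplicity.ZERO_OR_MANY: "*",
    Multiplicity.NOT_DETERMINED: "*",
}


def _constraint(link: UniqueTypeLink, shaped: set) -> tuple[str, str]:
    """One triple constraint as (code, end-of-line comment)."""
    if link.object_kind is ObjectKind.DATATYPE:
        value = f"<{link.object_type}>"
    elif link.object_kind is ObjectKind.CLASS and str(link.object_type) in shaped:
        value = f"@<{link.object_type}>"
    else:
        value = "IRI"
    card = _CARDINALITY[link.forward]
    code = f"<{link.predicate}> {value}{' ' + card if card else ''}"
    comments = []
    if link.object_kind is ObjectKind.EXTERNAL:
        comments.append(f"external reference into {link.object_type}")
    elif link.object_kind is ObjectKind.INVALID:
        comments.append(f"invalid: untyped subjects under {link.object_type}")
    elif link.object_kind is ObjectKind.CLASS and str(link.object_type) not in shaped:
        comments.append(f"class without instances: {link.object_type}")
    if link.forward is Multiplicity.NOT_DETERMINED:
        comments.append("WARNING: multiplicity not determined")
    return code, "; ".join(comments)


def _line(indent: str, code: str, sep: str, comment: str) -> str:
    return f"{indent}{code}{sep}" + (f"  # {comment}" if comment else "")


def serialize_shex(s: StructureGraph) -> str:
    tree = s.class_tree
    shaped = {str(c) for c in tree.classes if tree.instance_count(c) > 0}
    out = [
        "# Shape schema derived from the recovered structure",
        "PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>",
        "",
    ]
    for cp_owner in sorted(shaped):
        properties = [cp for cp in s.class_properties if str(cp.owner_class) == cp_owner]
        out.append(f"<{cp_owner}> {{")
        for pi, cp in enumerate(properties):
            sep = " ;" if pi < len(properties) - 1 else ""
            if len(cp.links) == 1:
                code, comment = _constraint(cp.links[0], shaped)
                out.append(_line("  ", code, sep, comment))
            else:
                out.append("  (")
                for i, link in enumerate(cp.links):
                    bar = " |" if i < len(cp.links) - 1 else ""
                    code, comment = _constraint(link, shaped)
                    out.append(_line("    ", code, bar, comment))
                out.append(f"  ){sep}")
        out.append("}")
        out.append("")
    return "\n".join(out)


def export_shex(s: StructureGraph, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_shex(s))
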