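"""Independent brute-force recount of unique type links from raw triples.

Deliberately written against plain triples with naive data structures —
no code shared with rdfstruct.recovery — so it can serve as the oracle for
recovered counts and multiplicities.
"""

from __future__ import annotations

from rdfstruct.rdf import IRI, Literal

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
SUBCLASS = "http://www.w3.org/2000/01/rdf-schema#subClassOf"
SAMEAS = "http://www.w3.org/2002/07/owl#sameAs"
SCHEMA = {RDF_TYPE, SUBCLASS, SAMEAS}


def recount(triples, namespaces):
    """Return {(subject_type, predicate, object_type, kind_name):
    (count, forward, reverse)} computed by definition."""
    types: dict = {}
    for s, p, o in triples:
        if str(p) == RDF_TYPE and isinstance(o, IRI):
            types.setdefault(s, set()).add(o)
    totals: dict = {}
    for s, ts in types.items():
        for t in ts:
            totals[t] = totals.get(t, 0) + 1

    def classify(o):
        if isinstance(o, Literal):
            return [(str(o.datatype), "datatype")]
        if o in types:
            return [(str(t), "class") for t in sorted(types[o])]
        for ns in namespaces:
            if str(o).startswith(ns):
                return [(ns, "invalid")]
        iri = str(o)
        if "://" in iri:
            scheme, rest = iri.split("://", 1)
            prefix = scheme + "://" + rest.split("/", 1)[0] + "/"
        else:
            prefix = iri
        return [(prefix, "external")]

    registries: dict = {}
    for s, p, o in triples:
        if str(p) in SCHEMA:
            continue
        for st in sorted(types.get(s, ())):
            for ot, kind in classify(o):
                registries.setdefault((str(st), str(p), ot, kind), set()).add((s, o))

    def bounds(total, groups):
        lower = 1 if len(groups) == total else 0
        upper = "1" if max(len(g) for g in groups.values()) == 1 else "N"
        return f"{lower}..{upper}"

    out = {}
    for key, registry in registries.items():
        st, p, ot, kind = key
        if kind == "invalid":
            fwd = rev = "not determined"
        else:
            per_subject: dict = {}
            for s, o in registry:
                per_subject.setdefault(s, set()).add(o)
            fwd = bounds(totals[IRI(st)], per_subject)
            if kind == "class":
                per_object: dict = {}
                for s, o in registry:
                    per_object.setdefault(o, set()).add(s)
                rev = bounds(totals[IRI(ot)], per_object)
            else:
                rev = "not determined"
        out[key] = (len(registry), fwd, rev)
    return out


def structure_as_dict(structure):
    """Recovered links in the oracle's key/value shape for comparison."""
    return {
        (str(l.subject_type), str(l.predicate), str(l.object_type), l.object_kind.value):
        (l.count, l.forward.value, l.reverse.value)
        for l in structure.links
    }
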