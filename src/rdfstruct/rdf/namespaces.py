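"""Well-known vocabulary IRIs."""

from .terms import IRI


class _NS:
    def __init__(self, base: str):
        self._base = base

    def __getattr__(self, name: str) -> IRI:
        return IRI(self._base + name)

    def __getitem__(self, name: str) -> IRI:
        return IRI(self._base + name)

    def __str__(self) -> str:
        return self._base


RDF = _NS("http://www.w3.org/1999/02/22-rdf-syntax-ns#")
RDFS = _NS("http://www.w3.org/2000/01/rdf-schema#")
OWL = _NS("http://www.w3.org/2002/07/owl#")
XSD = _NS("http://www.w3.org/2001/XMLSchema#")

RDF_TYPE = RDF.type
RDFS_SUBCLASSOF = RDFS.subClassOf
OWL_SAMEAS = OWL.sameAs

#: predicates that describe schema rather than instance data
SCHEMA_PREDICATES = frozenset({RDF_TYPE, RDFS_SUBCLASSOF, OWL_SAMEAS})

# vocabulary of the structure export (see exporters.structure_rdf)
STRUCT = _NS("https://w3id.org/rdf-structure#")
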