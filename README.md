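# rdfstruct

Recover the latent schema ("structure") of an RDF resource — its classes,
predicates, typed links and their multiplicities — simplify that structure
over the class hierarchy, and export it as structure-RDF, XGMML (Cytoscape
network), OWL 2, and ShEx compact syntax, together with a
structural-integrity report.

The input is either a set of local RDF files (Turtle, RDF/XML, N-Triples) or
a SPARQL 1.1 endpoint. For every `(subject type, predicate, object type)`
combination observed in the instance data the tool records a *unique type
link* with its occurrence count and a coarse cardinality (*multiplicity*) in
both directions: `1..1`, `1..N`, `0..1`, `0..N`, or *not determined* (links
to untyped in-namespace subjects, or predicates whose retrieval was
truncated). A per-predicate merge then folds links over the `subClassOf`
hierarchy (with `owl:sameAs` treated as mutual subclassing) so that sibling
links lift to their common ancestor classes, keeping the network view
readable without losing coverage.

## Command line

```sh
# recover + simplify + export
rdfstruct recover --input data.ttl --namespace http://my.resource.org/ \
    --rdf structure.ttl --xgmml network.xgmml --owl schema.owl \
    --shex shapes.shex --report integrity.txt

# against a SPARQL endpoint, limiting per-predicate retrieval
rdfstruct recover --endpoint http://host/sparql --namespace http://my.resource.org/ \
    --limit 100000 --xgmml network.xgmml

# re-export a saved structure without touching the source
rdfstruct export structure.ttl --shex shapes.shex

# synthetic test graphs and the built-in worked examples
rdfstruct fixture out.ttl --seed 7
rdfstruct fixture gene.ttl --preset gene_chromosome

# integrity report only
rdfstruct report --input data.ttl --namespace http://my.resource.org/
```

`--no-simplify` skips the hierarchy merge; `--hide-concepts` and
`--show-datatypes` control the network view; `--include-inverse` adds
reverse-multiplicity restrictions to the OWL export. All options can also be
given in a YAML file via `--config` (flags win). Exit codes: 0 success,
1 runtime error, 2 configuration error.

## Library

```python
from rdfstruct import ResourceHandle, recover, simplify
from rdfstruct.exporters import export_xgmml

handle = ResourceHandle(files=("data.ttl",), namespaces=("http://my.resource.org/",))
structure = simplify(recover(handle))
for link in structure.links:
    print(link.subject_type, link.predicate, link.object_type,
          link.forward, link.reverse, link.count)
export_xgmml(structure, "network.xgmml")
```

The package is self-contained: `rdfstruct.rdf` provides the RDF term model,
an in-memory graph, and Turtle / N-Triples / RDF-XML readers and writers;
`rdfstruct.sparql` is a minimal SPARQL-protocol client, and
`rdfstruct.testing.LocalEndpoint` serves any in-memory graph as a local
SPARQL endpoint for tests.

## Tests and acceptance report

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates all inputs from the given seed, re-runs
the full pipeline, and verifies the worked-example multiplicities, the three
hierarchy-merge cases, equivalence with an independent brute-force recount
on 200 random graphs, the simplification invariants (idempotence, count
conservation, coverage preservation, non-expansion, determinism), the
structure-RDF round trip and its triple budget, the validity of the XGMML /
OWL / ShExC outputs, exact integrity-finding counts, and file-vs-endpoint
backend equivalence. It exits non-zero if any check fails. There are no
numeric reference targets (the tool's published summary statistics were
measured against external, version-dependent resources), so the JSON report
contains no target entries.
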