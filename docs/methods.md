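# Methods

## The conversion model

A GPML document is parsed into a typed in-memory pathway model
(`PathwayModel`: data nodes, interactions, free labels, organism metadata)
and then serialized into RDF twice, at two levels of meaning.

**Graphical layer.** Each markup element is mapped one-to-one onto the
`gpml:` vocabulary (`http://vocabularies.wikipathways.org/gpml#`). The
mapping is information-preserving by construction: a reverse mapping
(`datanodes_from_gpml_graph`) reconstructs every DataNode field except
document order, and the test suite asserts this on generated corpora.
Literal typing follows the printed conventions of the source data:
coordinates are `xsd:float`, z-order `xsd:integer`, text labels are
language-tagged `@en`, and xref database names are `xsd:string`-typed so
that stock queries matching `"PubChem-compound"^^xsd:string` answer
correctly under RDF term equality.

**Biological layer.** The `wp:` vocabulary
(`http://vocabularies.wikipathways.org/wp#`) captures what the drawing
means: entity classes per data-node type, pathway membership
(`skos:member`, `dcterms:isPartOf`), organism (taxon URI in `wp:organism`,
name literal in `wp:organismName` — the stock species query selects both),
and interactions typed by their arrowhead semantics. The layer is produced
by rule-based rewriting with two interchangeable engines:

* a procedural engine walking the pathway model, and
* a declarative engine executing `data/rules/gpml_to_wp.rq`, a sequence of
  SPARQL CONSTRUCT queries over the graphical-layer graph alone.

The two engines are required to be set-equal on every input; this
equivalence is the package's core oracle and is enforced by unit,
property (hypothesis) and acceptance tests. It is the reason the graphical
layer carries `gpml:nodeType`, `gpml:isPartOf`, `gpml:source`/`gpml:target`
(resolved endpoint URIs) and the xref triples: the declarative engine may
only see the graph, so everything the rules need must be in it.

Rule application is monotone (the output is the union of input and
produced triples), order-independent within a pass (no rule consumes
another rule's output), and idempotent for the default rule set.

### Subject URIs

Data nodes annotated with a database cross-reference use their
identifiers.org URI as subject; unannotated nodes, interactions and labels
get pathway-local URIs
(`http://rdf.wikipathways.org/Pathway/{wp_id}/{graph_id}`). Two boxes
annotated with the same accession therefore share a subject — the
`gpml:graphId` triples keep occurrences distinguishable — and a
`pathway_local_always` policy is available when lossless per-box graphics
work matters. The synthetic generator keeps accessions unique within a
pathway so corpus-level counting oracles are unaffected by merging.

### Arrowhead semantics

The mapping from line decorations to interaction classes is an explicit,
overridable table: `Arrow` → `wp:DirectedInteraction`, `TBar` and
`mim-inhibition` → `wp:Inhibition`, `mim-conversion` → `wp:Conversion`,
`mim-catalysis` → `wp:Catalysis`, plain or unknown decorations →
undirected `wp:Interaction`. Unknown decoration strings are preserved
verbatim in the model and the graphical layer, never dropped. Because the
table is non-injective (two decorations mean inhibition), the
biology-level round trip (`reverse_to_gpml ∘ apply_rules`) is checked at
the interaction-class level, not the raw decoration level; node type,
label and xref round-trip exactly.

Interaction ends bound to an anchor on another line (catalysis drawn onto
a conversion) produce `wp:participants` to that line's interaction
instance; ends bound to nothing leave the instance typed with only the
bound role and a logged warning. Dropping such curation artifacts would
lose data silently.

### Identifier predicates

Annotated nodes carry three identifier triples: `dc:identifier` with the
identifiers.org URI, `dcterms:identifier` with the bare accession, and
`dc:source` with the database name. Both Dublin Core namespaces are
emitted deliberately — different stock queries use different ones, and
both must answer. Unified-identifier (`wp:bdb*`) triples are routed by
node class: gene-type nodes (gene product, protein, RNA) may only receive
Entrez Gene / Ensembl / UniProt targets, metabolites only HMDB /
ChemSpider; other classes receive none. A node whose own annotation is
already in a unified system gets a self-referential `wp:bdb*` triple so
unified joins need no special-casing. Query-expansion-style mapping (a
service rewriting queries at run time) is intentionally not implemented;
pre-computed unified identifiers trade triple redundancy for zero run-time
dependencies.

## Parsing decisions

* Missing `GraphId` attributes get deterministic synthesized ids
  (`auto-` + zero-padded document ordinal); duplicates are a hard error.
* Any GPML namespace URI is accepted (the dialect has several dated
  namespaces); the namespace found is recorded as provenance. Provenance
  does not participate in model equality.
* An `Xref` with an empty `Database` or `ID` is treated as absent, with a
  warning: only genuinely annotated nodes are unified.
* The WikiPathways accession is not part of standard GPML (production
  converters receive it out-of-band); `parse_gpml` takes it as an argument
  or from a `WPID` attribute our writer emits, falling back to `WP0`.
* The organism taxon URI is resolved from a shipped species table (name →
  NCBI taxonomy id) covering the commonly curated species; unknown names
  simply lack a taxon triple.
* Coordinates are kept exactly as parsed; no unit conversion; origin is
  top-left with y increasing downward, as in the source format.

## Synthetic corpus generator

`gpml2rdf.fixtures.generate_corpus` emulates the structure of a curated
pathway collection: pathways drawn from a pool of 15 species, 6–18 data
nodes each, a node-type mix of roughly 40% gene products, 18% proteins,
22% metabolites and small fractions of RNAs, complexes, pathway links and
untyped boxes, 85% of eligible nodes annotated with a database fitting
their type, edges on 8% of node pairs with a realistic arrowhead mix, and
an identifier-mapping fan-out of 0–3 unified ids per annotation. These
defaults are fixed design choices of the package; tests always pin seeds.
The ground-truth manifest (species, node, edge and mapping-row lists) is
written *before* any XML rendering, which makes it a non-circular oracle
for every count-based check. Acceptance-level checks run on a 50-pathway
corpus and a 200-pathway scaling run — sizes chosen so the full pipeline
(including the brute-force query oracle, which is exponential in pattern
count) stays comfortably fast on a single CPU while still exercising
multi-species aggregation.

What the generator does **not** emulate: malformed XML in the wild (beyond
targeted hand-written invalid fixtures), groups/shapes/states and graphics
styling beyond geometry, curation noise such as inconsistent database name
spellings, and biological realism of the wiring (edges are random pairs,
not reaction chemistry). Passing tests therefore demonstrate structural
and semantic correctness of the conversion, not robustness to every
real-world curation artifact.

## Queries

Stored queries are shipped verbatim as `.rq` files. The species-count
query exists twice: the original endpoint dialect (pre-SPARQL-1.1
aggregate syntax, shipped for fidelity, refused at run time) and a
normalized SPARQL 1.1 variant that is executed. Federated queries (with
`SERVICE` clauses against DisGeNET and the EBI Expression Atlas) are
first-class documentation but never executed: remote endpoints are outside
this package's reliability envelope, and `run_query` refuses them
explicitly. Engine results are validated against a brute-force
triple-pattern join oracle implemented independently of the query engine.

## Known limitations

* GPML Groups, Shapes, States and GraphicalLines are not modelled; only
  DataNode/Interaction/Label, which carry the biological content.
* Reverse conversion assigns grid-layout coordinates; it restores the
  biology, not the original drawing.
* One pathway per reverse conversion: multi-pathway graphs convert the
  lexicographically first pathway subject.
* The identifiers.org template table is a static snapshot (overridable);
  the live namespace registry evolves.
* No OWL reasoning or transitive closure — single-pass rule application
  only.
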