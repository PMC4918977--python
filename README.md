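# gpml2rdf

Convert biological pathway diagrams from GPML (Graphical Pathway Markup
Language) into semantic-web RDF, so that curated pathway knowledge can be
joined with other life-science resources through SPARQL.

A pathway diagram carries two kinds of knowledge at once: the drawing
(boxes, lines, coordinates, z-order) and the biology it depicts (this box
is the metabolite glucose; this arrow is a directed interaction from A to
B). `gpml2rdf` represents both, in two layered vocabularies:

* **`gpml:` — the graphical layer.** A one-to-one mapping of GPML markup
  elements and attributes onto RDF classes and properties. Every DataNode
  becomes a subject with `gpml:graphId`, `gpml:ZOrder`, `gpml:centerX`, …
  as typed literals. This layer preserves enough information to re-render
  or re-curate the diagram.
* **`wp:` — the biological layer.** Produced from the graphical layer by
  rule-based graph rewriting (each rule is a SPARQL CONSTRUCT query: match
  a graphical pattern, produce its biological interpretation). Boxes become
  `wp:Metabolite` / `wp:GeneProduct` / `wp:Protein` / …, membership becomes
  `skos:member` / `dcterms:isPartOf`, and an arrowheaded line between two
  boxes becomes a `wp:DirectedInteraction` with `wp:source` and
  `wp:target`. Layout is disregarded.

Subjects are resolvable identifiers.org URIs wherever a database
cross-reference allows it — the glucose box annotated `ChEBI:CHEBI:4167`
*is* `<http://identifiers.org/chebi/CHEBI:4167>`. On top of this the
package provides:

* **Unified identifiers** (`gpml2rdf.idmap`): every annotated entity is
  mapped ahead of time (via a 4-column TSV mapping table) to a small set of
  canonical systems — Entrez Gene, Ensembl, UniProt for gene products;
  HMDB, ChemSpider for compounds — materialised as partially redundant
  `wp:bdbEntrezGene` / `wp:bdbEnsembl` / … triples, so that cross-resource
  joins need no live mapping service.
* **VoID dataset headers** (`gpml2rdf.dataset_meta`) stating the license
  (CC-BY 3.0) and the exact triple count of each emitted dataset.
* **Stock SPARQL queries** (`gpml2rdf.queries`): species/pathway counts,
  gene products per pathway, compounds across pathways — plus two federated
  queries (DisGeNET disease genes, EBI Expression Atlas) shipped as
  documentation and deliberately never executed locally.
* **A deterministic synthetic-corpus generator** (`gpml2rdf.fixtures`)
  that produces GPML files together with a ground-truth manifest, so the
  whole stack is testable without downloading anything.

## Worked example

```python
import gpml2rdf as g
from gpml2rdf import fixtures

model = g.parse_gpml(fixtures.paper_fixture("glucose_node"))
graph = g.apply_rules(g.emit_gpml_layer(model), model=model)
print(g.serialize(graph, "turtle").decode())
```

prints (abridged to the glucose subject):

```turtle
<http://identifiers.org/chebi/CHEBI:4167> a gpml:DataNode,
        wp:Metabolite ;
    rdfs:label "Glucose"@en ;
    dc:identifier <http://identifiers.org/chebi/CHEBI:4167> ;
    dc:source "ChEBI"^^xsd:string ;
    dcterms:identifier "CHEBI:4167" ;
    dcterms:isPartOf <http://identifiers.org/wikipathways/WP534> ;
    gpml:ZOrder 32768 ;
    gpml:centerX "279.0"^^xsd:float ;
    gpml:centerY "468.0"^^xsd:float ;
    gpml:graphId "dba83" ;
    ...
```

Read it layer by layer: the graphical layer says there is a box with graph
id `dba83` at (279, 468) drawn at z-order 32768; the biological layer says
that box is the metabolite glucose, identified by ChEBI accession
CHEBI:4167, and a member of the glycolysis pathway WP534
(`<.../wikipathways/WP534> skos:member <.../chebi/CHEBI:4167>`).

The same pipeline from the shell:

```
gpml2rdf generate --seed 5 --n-pathways 100 --out corpus/
gpml2rdf convert corpus/ --out rdf/ --mapping corpus/mapping.tsv
gpml2rdf query species_pathway_counts --rdf rdf/
```

The last command prints a TSV with one row per species and the number of
converted pathways for it, answered from the `wp:` layer alone.

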