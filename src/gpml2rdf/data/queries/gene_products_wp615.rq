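# Get all gene products on a particular pathway (WP615 as an example).
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs:    <http://www.w3.org/2000/01/rdf-schema#>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

SELECT DISTINCT ?pathway ?label
WHERE {
  ?geneProduct a wp:GeneProduct .
  ?geneProduct rdfs:label ?label .
  ?geneProduct dcterms:isPartOf ?pathway .
  ?pathway rdf:type wp:Pathway .
  FILTER regex(str(?pathway), "WP615") .
}
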