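# Return all PubChem compounds in the pathway set and the pathways they are in.
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX dc:      <http://purl.org/dc/elements/1.1/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX xsd:     <http://www.w3.org/2001/XMLSchema#>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

SELECT DISTINCT ?identifier ?pathway
WHERE {
  ?concept dcterms:isPartOf ?pathway .
  ?concept dc:source "PubChem-compound"^^xsd:string .
  ?concept dc:identifier ?identifier .
  ?pathway rdf:type wp:Pathway .
}
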