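# FEDERATED — documentation only; never executed by this package.
# From DisGeNET get disease-gene pairs on asthma and get all pathways where
# these genes have a role.  Requires the remote DisGeNET SPARQL endpoint.
PREFIX identifiers: <http://identifiers.org/ensembl/>
PREFIX atlas:   <http://rdf.ebi.ac.uk/resource/atlas/>
PREFIX efo:     <http://www.ebi.ac.uk/efo/>
PREFIX sio:     <http://semanticscience.org/resource/>
PREFIX skos:    <http://www.w3.org/2004/02/skos/core#>
PREFIX ncit:    <http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#>
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs:    <http://www.w3.org/2000/01/rdf-schema#>
PREFIX dc:      <http://purl.org/dc/elements/1.1/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

SELECT DISTINCT ?wpId ?pwtitle
  (group_concat(distinct ?wpgene_identifier; separator = "; ") as ?wpgenes)
WHERE {
  SERVICE <http://rdf.disgenet.org/sparql/> {
    GRAPH <http://rdf.disgenet.org> {
      ?gda sio:SIO_000628 ?gene, ?disease .
      ?gene rdf:type ncit:C16612 ; rdfs:label ?geneLabel .
      ?disease rdf:type ncit:C7057 ; rdfs:label ?diseaseLabel .
      FILTER regex(?diseaseLabel, "asthma", "i")
      ?gene sio:SIO_010078 ?protein .
    }
  }
  ?wpgene wp:bdbEntrezGene ?gene .
  ?wpgene dcterms:identifier ?wpgene_identifier .
  ?wpgene dcterms:isPartOf ?pathway .
  ?pathway a wp:Pathway .
  ?pathway dc:identifier ?wpId .
  ?pathway dc:title ?pwtitle .
}
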