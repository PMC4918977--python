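# FEDERATED — documentation only; never executed by this package.
# For the genes differentially expressed in asthma (found in the EBI
# Expression Atlas), get the gene products associated to a pathway.
PREFIX identifiers: <http://identifiers.org/ensembl/>
PREFIX atlas:      <http://rdf.ebi.ac.uk/resource/atlas/>
PREFIX atlasterms: <http://rdf.ebi.ac.uk/terms/atlas/>
PREFIX efo:        <http://www.ebi.ac.uk/efo/>
PREFIX rdf:        <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs:       <http://www.w3.org/2000/01/rdf-schema#>
PREFIX dc:         <http://purl.org/dc/elements/1.1/>
PREFIX dcterms:    <http://purl.org/dc/terms/>
PREFIX wp:         <http://vocabularies.wikipathways.org/wp#>

SELECT DISTINCT ?wpURL ?pwTitle ?Ensembl ?EntrezGene ?expressionValue ?pvalue
WHERE {
  SERVICE <https://www.ebi.ac.uk/rdf/services/atlas/sparql> {
    ?factor rdf:type efo:EFO_0000270 .
    ?value atlasterms:hasFactorValue ?factor .
    ?value atlasterms:isMeasurementOf ?probe .
    ?value atlasterms:pValue ?pvalue .
    ?value rdfs:label ?expressionValue .
    ?probe atlasterms:dbXref ?dbXref .
  }
  ?pwElement dcterms:isPartOf ?pathway .
  ?pathway dc:title ?pwTitle .
  ?pathway dc:identifier ?wpURL .
  ?pwElement wp:bdbEnsembl ?Ensembl .
  ?pwElement wp:bdbEntrezGene ?EntrezGene .
}
ORDER BY ASC(?pvalue)
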