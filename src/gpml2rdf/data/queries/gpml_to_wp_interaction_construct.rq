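# CONSTRUCT query converting a drawn interaction (a line with an arrowhead,
# described by its spatial GPML properties) into its biological
# interpretation: a directed interaction with a source and a target.
# The full default rule set lives in rules/gpml_to_wp.rq.
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX gpml:    <http://vocabularies.wikipathways.org/gpml#>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

CONSTRUCT {
  ?interaction rdf:type wp:DirectedInteraction .
  ?interaction wp:source ?source .
  ?interaction wp:target ?target .
  ?interaction dcterms:isPartOf ?pathway .
}
WHERE {
  ?interaction rdf:type gpml:Interaction ;
               gpml:arrowHead "Arrow" ;
               gpml:isPartOf ?pathway ;
               gpml:source ?source ;
               gpml:target ?target .
  ?source rdf:type gpml:DataNode .
  ?target rdf:type gpml:DataNode .
}
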