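# List the species captured in the pathway set and the number of pathways
# per species.  SPARQL 1.1 normalization of the legacy endpoint query
# (explicit GROUP BY; see species_pathway_counts_legacy.rq for the original
# dialect).
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX dc:      <http://purl.org/dc/elements/1.1/>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

SELECT DISTINCT ?organism ?label (COUNT(DISTINCT ?pathway) AS ?numberOfPathways)
WHERE {
  ?pathway dc:title ?title .
  ?pathway wp:organism ?organism .
  ?pathway wp:organismName ?label .
  ?pathway rdf:type wp:Pathway .
}
GROUP BY ?organism ?label
ORDER BY DESC(?numberOfPathways)
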