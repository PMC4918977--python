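# List the species captured in the pathway set and the number of pathways
# per species — verbatim endpoint dialect (pre-SPARQL-1.1 aggregate syntax,
# as accepted by Virtuoso).  Shipped for fidelity; not executable by a
# strict SPARQL 1.1 engine.  Use species_pathway_counts.rq instead.
SELECT DISTINCT ?organism ?label count(?pathway) as ?numberOfPathways
WHERE {
  ?pathway dc:title ?title .
  ?pathway wp:organism ?organism .
  ?pathway wp:organismName ?label .
  ?pathway rdf:type wp:Pathway .
}
ORDER BY DESC(?numberOfPathways)
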