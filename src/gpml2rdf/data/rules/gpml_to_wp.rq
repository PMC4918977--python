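# Default GPML-layer -> WP-layer rewrite rules.
#
# Each rule is a SPARQL CONSTRUCT query converting one graphical graph
# pattern into its biological interpretation.  Rules are independent and
# side-effect free: they match only GPML-vocabulary triples and produce only
# WP-layer triples, so applying them in any order (or twice) yields the same
# statement set.

PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs:    <http://www.w3.org/2000/01/rdf-schema#>
PREFIX skos:    <http://www.w3.org/2004/02/skos/core#>
PREFIX dc:      <http://purl.org/dc/elements/1.1/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX xsd:     <http://www.w3.org/2001/XMLSchema#>
PREFIX gpml:    <http://vocabularies.wikipathways.org/gpml#>
PREFIX wp:      <http://vocabularies.wikipathways.org/wp#>

# RULE pathway
CONSTRUCT {
  ?p rdf:type wp:Pathway .
  ?p dc:title ?title .
  ?p rdfs:label ?label .
}
WHERE {
  ?p rdf:type gpml:Pathway ; dc:title ?title .
  BIND(STRLANG(STR(?title), "en") AS ?label)
}

# RULE pathway-organism
CONSTRUCT { ?p wp:organism ?organism . }
WHERE { ?p rdf:type gpml:Pathway ; gpml:organism ?organism . }

# RULE pathway-organism-name
CONSTRUCT { ?p wp:organismName ?name . }
WHERE { ?p rdf:type gpml:Pathway ; gpml:organismName ?name . }

# RULE data-node-class
# A DataNode is a chemical compound, gene product, protein, RNA, complex or
# a link to another pathway; untyped boxes stay generic wp:DataNode.
CONSTRUCT { ?n rdf:type ?class . }
WHERE {
  ?n rdf:type gpml:DataNode ; gpml:nodeType ?t .
  VALUES (?t ?class) {
    ("GeneProduct" wp:GeneProduct)
    ("Protein"     wp:Protein)
    ("Rna"         wp:Rna)
    ("Metabolite"  wp:Metabolite)
    ("Pathway"     wp:Pathway)
    ("Complex"     wp:Complex)
    ("Unknown"     wp:DataNode)
  }
}

# RULE data-node-label
CONSTRUCT { ?n rdfs:label ?label . }
WHERE { ?n rdf:type gpml:DataNode ; rdfs:label ?label . }

# RULE data-node-membership
CONSTRUCT {
  ?n dcterms:isPartOf ?p .
  ?p skos:member ?n .
}
WHERE {
  ?n rdf:type gpml:DataNode ; gpml:isPartOf ?p .
  ?p rdf:type gpml:Pathway .
}

# RULE data-node-identifier-uri
CONSTRUCT { ?n dc:identifier ?uri . }
WHERE { ?n rdf:type gpml:DataNode ; gpml:xref ?uri . }

# RULE data-node-identifier-accession
CONSTRUCT { ?n dcterms:identifier ?accession . }
WHERE { ?n rdf:type gpml:DataNode ; gpml:xrefId ?accession . }

# RULE data-node-identifier-source
CONSTRUCT { ?n dc:source ?database . }
WHERE { ?n rdf:type gpml:DataNode ; gpml:xrefDataSource ?database . }

# RULE interaction-class
# A line is interpreted by its arrowhead: plain arrows are directed
# interactions with a source and a target, T-bars inhibitions, MIM
# decorations their molecular-interaction-map meaning.
CONSTRUCT { ?i rdf:type ?class . }
WHERE {
  ?i rdf:type gpml:Interaction ; gpml:arrowHead ?a .
  VALUES (?a ?class) {
    ("Line"            wp:Interaction)
    ("Arrow"           wp:DirectedInteraction)
    ("TBar"            wp:Inhibition)
    ("mim-conversion"  wp:Conversion)
    ("mim-catalysis"   wp:Catalysis)
    ("mim-inhibition"  wp:Inhibition)
  }
}

# RULE interaction-class-other
# Unknown arrowhead decorations keep their line as an undirected interaction.
CONSTRUCT { ?i rdf:type wp:Interaction . }
WHERE {
  ?i rdf:type gpml:Interaction ; gpml:arrowHead ?a .
  FILTER (?a NOT IN ("Line", "Arrow", "TBar",
                     "mim-conversion", "mim-catalysis", "mim-inhibition"))
}

# RULE interaction-membership
CONSTRUCT { ?i dcterms:isPartOf ?p . }
WHERE { ?i rdf:type gpml:Interaction ; gpml:isPartOf ?p . }

# RULE interaction-source
CONSTRUCT { ?i wp:source ?s . }
WHERE { ?i rdf:type gpml:Interaction ; gpml:source ?s . ?s rdf:type gpml:DataNode . }

# RULE interaction-target
CONSTRUCT { ?i wp:target ?t . }
WHERE { ?i rdf:type gpml:Interaction ; gpml:target ?t . ?t rdf:type gpml:DataNode . }

# RULE interaction-participants-source
# An end attached to an anchor on another line (e.g. catalysis touching a
# conversion) participates in that interaction.
CONSTRUCT { ?i wp:participants ?x . }
WHERE { ?i rdf:type gpml:Interaction ; gpml:source ?x . ?x rdf:type gpml:Interaction . }

# RULE interaction-participants-target
CONSTRUCT { ?i wp:participants ?x . }
WHERE { ?i rdf:type gpml:Interaction ; gpml:target ?x . ?x rdf:type gpml:Interaction . }
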