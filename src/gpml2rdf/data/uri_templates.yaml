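# identifiers.org URI templates per database / unified system name.
# The {id} slot receives the raw accession as curated (ChEBI accessions keep
# their "CHEBI:" prefix, as identifiers.org expects).
ChEBI: "http://identifiers.org/chebi/{id}"
HMDB: "http://identifiers.org/hmdb/{id}"
ChemSpider: "http://identifiers.org/chemspider/{id}"
PubChem-compound: "http://identifiers.org/pubchem.compound/{id}"
Entrez Gene: "http://identifiers.org/ncbigene/{id}"
EntrezGene: "http://identifiers.org/ncbigene/{id}"
NCBI Gene: "http://identifiers.org/ncbigene/{id}"
Ensembl: "http://identifiers.org/ensembl/{id}"
UniProt: "http://identifiers.org/uniprot/{id}"
Uniprot-TrEMBL: "http://identifiers.org/uniprot/{id}"
Uniprot-SwissProt: "http://identifiers.org/uniprot/{id}"
WikiPathways: "http://identifiers.org/wikipathways/{id}"
KEGG Compound: "http://identifiers.org/kegg.compound/{id}"
Taxonomy: "http://identifiers.org/taxonomy/{id}"
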