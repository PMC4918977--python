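"""Unified-identifier mapping: TSV loading, URI minting, routing, triple counts."""

import random

import pytest
from rdflib import URIRef

import gpml2rdf as g
from gpml2rdf import idmap
from gpml2rdf.idmap import (
    BDB_PREDICATES,
    COMPOUND_TARGETS,
    GENE_TARGETS,
    SYSTEM_SYNONYMS,
    UnifiedSystem,
    unified_ids_for_node,
)
from gpml2rdf.model import NodeType


class TestLoadMappingTsv:
    def test_single_row_lookup(self):
        mapping = g.load_mapping_tsv("ChEBI\tCHEBI:4167\tHMDB\tHMDB0000122\n")
        assert mapping.lookup("ChEBI", "CHEBI:4167") == {(UnifiedSystem.HMDB, "HMDB0000122")}

    def test_empty_table_all_lookups_empty(self):
        mapping = g.load_mapping_tsv("# just a comment\n\n")
        assert len(mapping) == 0
        assert mapping.lookup("ChEBI", "CHEBI:1") == set()

    def test_duplicate_rows_collapse_to_distinct_count(self):
        rng = random.Random(0)
        rows = [
            (f"ChEBI", f"CHEBI:{rng.randrange(50)}", "HMDB", f"HMDB{rng.randrange(20):07d}")
            for _ in range(1000)
        ]
        text = "\n".join("\t".join(r) for r in rows)
        mapping = g.load_mapping_tsv(text)
        assert len(mapping) == len(set(rows))

    def test_wrong_column_count_names_line(self):
        with pytest.raises(g.MappingLoadError, match="line 2"):
            g.load_mapping_tsv("a\tb\tHMDB\tc\nd\te\tf\n")

    def test_unknown_unified_system_rejected(self):
        with pytest.raises(g.MappingLoadError, match="KEGG"):
            g.load_mapping_tsv("a\tb\tKEGG\tc\n")


class TestMintUri:
    @pytest.mark.parametrize(
        "system,accession,expected",
        [
            ("ChEBI", "CHEBI:4167", "http://identifiers.org/chebi/CHEBI:4167"),
            ("WikiPathways", "WP534", "http://identifiers.org/wikipathways/WP534"),
            ("Entrez Gene", "1017", "http://identifiers.org/ncbigene/1017"),
        ],
    )
    def test_known_systems(self, system, accession, expected):
        assert str(g.mint_identifiers_org_uri(system, accession)) == expected

    def test_unknown_system_is_minting_error(self):
        with pytest.raises(g.MintingError):
            g.mint_identifiers_org_uri("MadeUpDb", "X1")

    def test_determinism(self):
        a = g.mint_identifiers_org_uri("HMDB", "HMDB0000122")
        assert a == g.mint_identifiers_org_uri("HMDB", "HMDB0000122")


class TestRouting:
    def test_gene_node_with_ensembl_mapping_gets_one_bdb_triple(self):
        mapping = g.load_mapping_tsv("Entrez Gene\t1017\tEnsembl\tENSG00000123374\n")
        model = g.PathwayModel(wp_id="WP1", title="t")
        model.data_nodes.append(
            g.DataNode(graph_id="a", text_label="CDK2", node_type=NodeType.GeneProduct,
                       xref=("Entrez Gene", "1017"))
        )
        graph = g.emit_unified_triples(model, mapping)
        ens = list(graph.subject_objects(BDB_PREDICATES[UnifiedSystem.Ensembl]))
        assert len(ens) == 1
        assert str(ens[0][1]) == "http://identifiers.org/ensembl/ENSG00000123374"

    def test_unmapped_metabolite_keeps_only_original_identifier(self):
        model = g.PathwayModel(wp_id="WP1", title="t")
        model.data_nodes.append(
            g.DataNode(graph_id="a", text_label="X", node_type=NodeType.Metabolite,
                       xref=("ChEBI", "CHEBI:999999"))
        )
        graph = g.emit_unified_triples(model, g.load_mapping_tsv(""))
        bdb = [t for t in graph if t[1] in BDB_PREDICATES.values()]
        assert bdb == []
        from rdflib.namespace import DC

        assert (None, DC.identifier, URIRef("http://identifiers.org/chebi/CHEBI:999999")) in graph

    def test_self_mapping_when_xref_already_unified(self):
        """An Ensembl-annotated gene gets wp:bdbEnsembl to itself, so
        unified-identifier joins need no special-casing."""
        model = g.PathwayModel(wp_id="WP1", title="t")
        model.data_nodes.append(
            g.DataNode(graph_id="a", text_label="G", node_type=NodeType.GeneProduct,
                       xref=("Ensembl", "ENSG00000123374"))
        )
        graph = g.emit_unified_triples(model, g.load_mapping_tsv(""))
        assert (
            URIRef("http://identifiers.org/ensembl/ENSG00000123374"),
            BDB_PREDICATES[UnifiedSystem.Ensembl],
            URIRef("http://identifiers.org/ensembl/ENSG00000123374"),
        ) in graph

    def test_gene_compound_routing_never_crosses(self, corpus):
        """No metabolite ever carries a gene-system predicate and vice versa."""
        models, _, mapping_tsv, _ = corpus
        mapping = g.load_mapping_tsv(mapping_tsv)
        gene_preds = {BDB_PREDICATES[s] for s in GENE_TARGETS}
        compound_preds = {BDB_PREDICATES[s] for s in COMPOUND_TARGETS}
        for model in models:
            graph = g.emit_unified_triples(model, mapping)
            from gpml2rdf.gpml_layer import DEFAULT_POLICY, node_subject

            for node in model.data_nodes:
                subject = node_subject(model, node, DEFAULT_POLICY)
                preds = {p for p in graph.predicates(subject, None)}
                if node.node_type is NodeType.Metabolite:
                    assert not (preds & gene_preds)
                elif node.node_type in (NodeType.GeneProduct, NodeType.Protein, NodeType.Rna):
                    assert not (preds & compound_preds)

    def test_bdb_triple_count_equals_manifest_fanout_sum(self, corpus):
        """Brute-force count oracle: per-node policy-filtered lookups, summed."""
        models, _, mapping_tsv, manifest = corpus
        mapping = g.load_mapping_tsv(mapping_tsv)
        bdb_preds = set(BDB_PREDICATES.values())
        for model, pw in zip(models, manifest["pathways"]):
            rows_by_xref: dict = {}
            for ssys, sid, usys, uid in pw["mapping_rows"]:
                rows_by_xref.setdefault((ssys, sid), set()).add((UnifiedSystem(usys), uid))
            expected = 0
            for node in pw["nodes"]:
                if node["xref"] is None:
                    continue
                key = tuple(node["xref"])
                unified = set(rows_by_xref.get(key, set()))
                if key[0] in SYSTEM_SYNONYMS:
                    unified.add((SYSTEM_SYNONYMS[key[0]], key[1]))
                allowed = idmap.DEFAULT_POLICY.targets_for(NodeType(node["type"]))
                expected += len({u for u in unified if u[0] in allowed})
            graph = g.emit_unified_triples(model, mapping)
            assert len([t for t in graph if t[1] in bdb_preds]) == expected

    def test_redundancy_bound_per_node(self):
        mapping = g.load_mapping_tsv(
            "ChEBI\tCHEBI:1\tHMDB\tHMDB0000001\nChEBI\tCHEBI:1\tChemSpider\t123\n"
        )
        unified = unified_ids_for_node(NodeType.Metabolite, ("ChEBI", "CHEBI:1"), mapping)
        assert len(unified) <= len(mapping.lookup("ChEBI", "CHEBI:1"))
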