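"""Biological-layer rewriting: the two engines, their equivalence, and reversal."""

import pytest
from rdflib import Graph, URIRef
from rdflib.namespace import RDF, SKOS

import gpml2rdf as g
from gpml2rdf import fixtures, wp_layer
from gpml2rdf.vocab import WP
from gpml2rdf.wp_layer import ARROW_SEMANTICS_MAP, NODE_TYPE_MAP, arrow_class

WP534 = URIRef("http://identifiers.org/wikipathways/WP534")
CHEBI_GLUCOSE = URIRef("http://identifiers.org/chebi/CHEBI:4167")


def wp_only(model, rules=None):
    return set(wp_layer.wp_triples(g.emit_gpml_layer(model), model=model, rules=rules))


class TestApplyRules:
    def test_glucose_pathway_membership_triple_present(self, glucose_model, glucose_gpml_graph):
        full = g.apply_rules(glucose_gpml_graph, model=glucose_model)
        assert (WP534, SKOS.member, CHEBI_GLUCOSE) in full

    def test_intro_statements_are_a_subset_of_the_wp_layer(self, glucose_model, glucose_gpml_graph):
        intro = set(fixtures.paper_fixture("wp534_intro"))
        assert len(intro) == 3
        full = set(g.apply_rules(glucose_gpml_graph, model=glucose_model))
        assert intro <= full

    def test_no_interactions_means_no_roles(self, glucose_model):
        triples = wp_only(glucose_model)
        assert not [t for t in triples if t[1] in (WP.source, WP.target)]

    def test_fully_bound_directed_edges_have_both_roles(self, corpus_models, corpus_manifest):
        for model, pw in zip(corpus_models, corpus_manifest["pathways"]):
            triples = wp_only(model)
            with_source = {s for s, p, o in triples if p == WP.source}
            with_target = {s for s, p, o in triples if p == WP.target}
            assert len(with_source & with_target) == len(pw["edges"])

    def test_monotone_and_idempotent(self, corpus_models, default_rules):
        model = corpus_models[0]
        gpml_graph = g.emit_gpml_layer(model)
        once = g.apply_rules(gpml_graph, rules=default_rules)
        assert set(gpml_graph) <= set(once)
        twice = g.apply_rules(once, rules=default_rules)
        assert set(twice) == set(once)

    def test_declarative_equals_procedural_on_corpus(self, corpus_models, default_rules):
        """Core oracle: rule-file execution and the procedural engine are set-equal."""
        for model in corpus_models:
            gpml_graph = g.emit_gpml_layer(model)
            assert set(wp_layer.wp_triples(gpml_graph, model=model)) == set(
                wp_layer.wp_triples(gpml_graph, rules=default_rules)
            )

    def test_arrowhead_semantics_table(self):
        assert ARROW_SEMANTICS_MAP["Arrow"] == WP.DirectedInteraction
        assert ARROW_SEMANTICS_MAP["TBar"] == WP.Inhibition
        assert arrow_class(g.ArrowHead("Other", "mim-whatever")) == WP.Interaction
        assert set(NODE_TYPE_MAP) == set(g.NodeType)

    def test_unbound_end_gets_type_but_only_bound_role(self):
        model = g.PathwayModel(wp_id="WP6", title="t")
        model.data_nodes.append(g.DataNode(graph_id="a", text_label="A"))
        model.interactions.append(
            g.InteractionEdge(graph_id="e", source_ref="a", target_ref=None,
                              arrow_head=g.ArrowHead("Arrow"), waypoints=[(0, 0), (1, 1)])
        )
        triples = wp_only(model)
        subjects = {s for s, p, o in triples if o == WP.DirectedInteraction}
        assert len(subjects) == 1
        (edge_subject,) = subjects
        assert [t for t in triples if t[0] == edge_subject and t[1] == WP.source]
        assert not [t for t in triples if t[1] == WP.target]

    def test_anchor_bound_end_becomes_participants(self, default_rules):
        """Catalysis drawn onto an anchor of a conversion line participates in it."""
        model = g.PathwayModel(wp_id="WP6", title="t")
        for gid in ("a", "b", "c"):
            model.data_nodes.append(g.DataNode(graph_id=gid, text_label=gid.upper()))
        model.interactions.append(
            g.InteractionEdge(graph_id="conv", source_ref="a", target_ref="b",
                              arrow_head=g.ArrowHead("MimConversion"),
                              anchors=["anc1"], waypoints=[(0, 0), (2, 0)])
        )
        model.interactions.append(
            g.InteractionEdge(graph_id="cat", source_ref="c", target_ref="anc1",
                              arrow_head=g.ArrowHead("MimCatalysis"),
                              waypoints=[(1, 1), (1, 0)])
        )
        proc = wp_only(model)
        participants = [t for t in proc if t[1] == WP.participants]
        assert len(participants) == 1
        assert str(participants[0][2]).endswith("/WP6/conv")
        # both engines agree on the anchor construction too
        assert proc == wp_only(model, rules=default_rules)


class TestLoadRules:
    def test_shipped_file_equals_builtin_engine_on_fixtures(
        self, glucose_model, default_rules
    ):
        gpml_graph = g.emit_gpml_layer(glucose_model)
        assert set(wp_layer.wp_triples(gpml_graph, rules=default_rules)) == set(
            wp_layer.wp_triples(gpml_graph, model=glucose_model)
        )

    def test_empty_file_yields_no_rules_and_identity_application(self, glucose_gpml_graph):
        rules = g.load_rules("")
        assert rules == []
        out = g.apply_rules(glucose_gpml_graph, rules=rules)
        assert set(out) == set(glucose_gpml_graph)

    def test_unbound_template_variable_is_load_error(self):
        text = (
            "# RULE broken\n"
            "CONSTRUCT { ?n <http://example.org/p> ?unbound . }\n"
            "WHERE { ?n a <http://example.org/C> . }\n"
        )
        with pytest.raises(g.RuleLoadError, match=r"\?unbound"):
            g.load_rules(text)

    def test_syntax_error_names_rule(self):
        with pytest.raises(g.RuleLoadError, match="oops"):
            g.load_rules("# RULE oops\nCONSTRUCT { WHERE }\n")

    def test_select_query_rejected_as_rule(self):
        with pytest.raises(g.RuleLoadError, match="CONSTRUCT"):
            g.load_rules("# RULE sel\nSELECT ?x WHERE { ?x a <http://example.org/C> }\n")


class TestReverse:
    @staticmethod
    def node_key(node):
        return (node.node_type.value, node.text_label, node.xref or ("", ""))

    def edge_key(self, model, edge):
        nodes = model.node_by_id()

        def end(ref):
            node = nodes.get(ref)
            return self.node_key(node) if node is not None else None

        return (end(edge.source_ref), end(edge.target_ref), str(arrow_class(edge.arrow_head)))

    def test_biology_round_trip_preserves_node_and_edge_multisets(self, corpus_models):
        for model in corpus_models:
            full = g.apply_rules(g.emit_gpml_layer(model), model=model)
            back = g.reverse_to_gpml(full)
            assert sorted(map(self.node_key, back.data_nodes)) == sorted(
                map(self.node_key, model.data_nodes)
            )
            assert sorted(self.edge_key(back, e) for e in back.interactions) == sorted(
                self.edge_key(model, e) for e in model.interactions
            )
            assert g.validate(back) == []

    def test_pathway_with_no_members_reverses_to_empty_node_list(self):
        graph = Graph()
        graph.add((WP534, RDF.type, WP.Pathway))
        back = g.reverse_to_gpml(graph)
        assert back.wp_id == "WP534" and back.data_nodes == []

    def test_intro_membership_graph_reverses_to_one_metabolite(self):
        back = g.reverse_to_gpml(fixtures.paper_fixture("wp534_intro"))
        assert len(back.data_nodes) == 1
        node = back.data_nodes[0]
        assert node.node_type is g.NodeType.Metabolite and node.text_label == "Glucose"

    def test_graph_without_pathway_subject_is_an_error(self):
        graph = Graph()
        graph.add((CHEBI_GLUCOSE, RDF.type, WP.Metabolite))
        with pytest.raises(wp_layer.ReverseConversionError):
            g.reverse_to_gpml(graph)

    def test_grid_layout_is_deterministic(self, corpus_models):
        full = g.apply_rules(g.emit_gpml_layer(corpus_models[0]), model=corpus_models[0])
        a = g.reverse_to_gpml(full)
        b = g.reverse_to_gpml(full)
        assert a == b
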