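"""Biological-layer RDF: rule-based rewriting of graphical-layer triples.

A drawn pathway encodes biology implicitly — a box annotated with a ChEBI
accession *is* a metabolite, a line with an arrowhead between two boxes *is*
a directed interaction with a source and a target.  This module makes that
meaning explicit by rewriting GPML-vocabulary triples into WP-vocabulary
triples.

Two interchangeable engines implement the same default rule set:

* a procedural engine that walks the :class:`~gpml2rdf.model.PathwayModel`;
* a declarative engine that executes the shipped rule file — a sequence of
  SPARQL CONSTRUCT queries — against the GPML-layer graph alone.

Their outputs must be set-equal on every input; the test suite enforces this
equivalence, which is the module's core correctness oracle.  Rule
application is monotone (never deletes statements), order-independent within
one pass, and idempotent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from rdflib import Graph, Literal, URIRef, Variable
from rdflib.namespace import DC, DCTERMS, RDF, RDFS, SKOS, XSD
from rdflib.plugins.sparql import prepareQuery

from .gpml_layer import (
    DEFAULT_POLICY,
    SubjectUriPolicy,
    local_subject,
    node_subject,
    pathway_subject,
)
from .idmap import MintingError, mint_identifiers_org_uri
from .model import (
    ArrowHead,
    DataNode,
    InteractionEdge,
    NodeType,
    PathwayModel,
)
from .vocab import GPML, PREFIXES, WP

log = logging.getLogger(__name__)

#: GPML data-node category -> WP class.  Total over the NodeType enum;
#: untyped boxes stay generic wp:DataNode.
NODE_TYPE_MAP: dict[NodeType, URIRef] = {
    NodeType.GeneProduct: WP.GeneProduct,
    NodeType.Protein: WP.Protein,
    NodeType.Rna: WP.Rna,
    NodeType.Metabolite: WP.Metabolite,
    NodeType.Pathway: WP.Pathway,
    NodeType.Complex: WP.Complex,
    NodeType.Unknown: WP.DataNode,
}

#: Arrowhead decoration -> WP interaction class.  Unknown decorations fall
#: back to the undirected wp:Interaction; this table is an explicit,
#: overridable default.
ARROW_SEMANTICS_MAP: dict[str, URIRef] = {
    "Arrow": WP.DirectedInteraction,
    "TBar": WP.Inhibition,
    "MimConversion": WP.Conversion,
    "MimCatalysis": WP.Catalysis,
    "MimInhibition": WP.Inhibition,
    "Line": WP.Interaction,
}


def arrow_class(arrow: ArrowHead) -> URIRef:
    return ARROW_SEMANTICS_MAP.get(arrow.kind, WP.Interaction)


class RuleLoadError(ValueError):
    pass


@dataclass
class RewriteRule:
    """One declarative graph rewrite: match a GPML pattern, produce WP triples.

    Stored as a SPARQL CONSTRUCT query; ``produce_template`` lists the
    template triples, ``match_vars`` the variables bound by the match
    pattern.  Every template variable must be matched (checked at load
    time).  Rules never delete statements.
    """

    name: str
    sparql_text: str
    produce_template: list = field(default_factory=list)
    match_vars: set = field(default_factory=set)

    def apply(self, graph: Graph) -> Graph:
        result = graph.query(self.sparql_text)
        out = Graph()
        for triple in result:
            out.add(triple)
        return out


def _algebra_vars(node, acc: set) -> None:
    """Collect every variable mentioned in a SPARQL algebra pattern tree."""
    if isinstance(node, Variable):
        acc.add(node)
    elif isinstance(node, dict):
        for key, value in node.items():
            if key == "template":
                continue
            _algebra_vars(value, acc)
    elif isinstance(node, (list, tuple, set, frozenset)):
        for item in node:
            _algebra_vars(item, acc)


def _parse_rule(name: str, text: str) -> RewriteRule:
    try:
        prepared = prepareQuery(text, initNs=PREFIXES)
    except Exception as exc:
        raise RuleLoadError(f"rule {name!r}: syntax error: {exc}") from exc
    algebra = prepared.algebra
    if algebra.name != "ConstructQuery":
        raise RuleLoadError(f"rule {name!r}: must be a CONSTRUCT query")
    template = list(algebra["template"])
    template_vars: set = set()
    _algebra_vars(template, template_vars)
    match_vars: set = set()
    _algebra_vars(algebra["p"], match_vars)
    unbound = template_vars - match_vars
    if unbound:
        names = ", ".join(sorted(f"?{v}" for v in unbound))
        raise RuleLoadError(f"rule {name!r}: template variable(s) {names} not bound in pattern")
    return RewriteRule(name=name, sparql_text=text, produce_template=template, match_vars=match_vars)


_RULE_HEADER = re.compile(r"^#\s*RULE\s+(\S+)\s*$", re.MULTILINE)


def load_rules(text: str) -> list[RewriteRule]:
    """Parse a rule file: '# RULE <name>' headers separating CONSTRUCT queries.

    A shared PREFIX block may precede the first rule.  An empty file yields
    an empty rule list.
    """
    matches = list(_RULE_HEADER.finditer(text))
    if not matches:
        if text.strip():
            raise RuleLoadError("rule file has content but no '# RULE <name>' headers")
        return []
    prologue = text[: matches[0].start()]
    prefix_block = "\n".join(
        line for line in prologue.splitlines() if line.strip().upper().startswith("PREFIX")
    )
    rules = []
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        body = text[m.end():end].strip()
        if not body:
            raise RuleLoadError(f"rule {m.group(1)!r}: empty body")
        rules.append(_parse_rule(m.group(1), prefix_block + "\n" + body))
    return rules


def default_rules() -> list[RewriteRule]:
    text = resources.files("gpml2rdf.data").joinpath("rules/gpml_to_wp.rq").read_text()
    return load_rules(text)


def _procedural_wp_triples(model: PathwayModel, policy: SubjectUriPolicy) -> Graph:
    """Reference procedural engine for the default rule set."""
    g = Graph()
    pw = pathway_subject(model)
    g.add((pw, RDF.type, WP.Pathway))
    g.add((pw, DC.title, Literal(model.title)))
    g.add((pw, RDFS.label, Literal(model.title, lang="en")))
    if model.organism_taxon_uri:
        g.add((pw, WP.organism, URIRef(model.organism_taxon_uri)))
    if model.organism_name:
        g.add((pw, WP.organismName, Literal(model.organism_name)))

    subj_of: dict[str, tuple[str, URIRef]] = {}
    for node in model.data_nodes:
        subj_of[node.graph_id] = ("node", node_subject(model, node, policy))
    for edge in model.interactions:
        uri = local_subject(model, edge.graph_id, policy)
        subj_of[edge.graph_id] = ("interaction", uri)
        for anchor_id in edge.anchors:
            subj_of[anchor_id] = ("interaction", uri)

    for node in model.data_nodes:
        s = subj_of[node.graph_id][1]
        g.add((s, RDF.type, NODE_TYPE_MAP[node.node_type]))
        g.add((s, RDFS.label, Literal(node.text_label, lang="en")))
        g.add((s, DCTERMS.isPartOf, pw))
        g.add((pw, SKOS.member, s))
        if node.xref is not None:
            database, accession = node.xref
            g.add((s, DCTERMS.identifier, Literal(accession)))
            g.add((s, DC.source, Literal(database, datatype=XSD.string)))
            try:
                g.add((s, DC.identifier, mint_identifiers_org_uri(database, accession)))
            except MintingError:
                pass

    for edge in model.interactions:
        s = subj_of[edge.graph_id][1]
        g.add((s, RDF.type, arrow_class(edge.arrow_head)))
        g.add((s, DCTERMS.isPartOf, pw))
        for role, ref in (("source", edge.source_ref), ("target", edge.target_ref)):
            if ref is None:
                log.debug("interaction %s has an unbound %s end", edge.graph_id, role)
                continue
            kind_uri = subj_of.get(ref)
            if kind_uri is None:
                continue
            kind, uri = kind_uri
            if kind == "node":
                g.add((s, WP.source if role == "source" else WP.target, uri))
            elif uri != s:
                g.add((s, WP.participants, uri))
    return g


def apply_rules(
    gpml_graph: Graph,
    model: Optional[PathwayModel] = None,
    rules: Optional[list[RewriteRule]] = None,
    policy: SubjectUriPolicy = DEFAULT_POLICY,
) -> Graph:
    """Union of the GPML-layer graph and the produced WP-layer triples.

    With ``rules=None`` and a model, the built-in procedural engine runs;
    with an explicit rule list, each rule's CONSTRUCT query is executed
    against ``gpml_graph`` (order-independent: no rule consumes another's
    output within a pass).
    """
    out = Graph()
    for prefix, base in PREFIXES.items():
        out.bind(prefix, base)
    for triple in gpml_graph:
        out.add(triple)
    for triple in wp_triples(gpml_graph, model=model, rules=rules, policy=policy):
        out.add(triple)
    return out


def wp_triples(
    gpml_graph: Graph,
    model: Optional[PathwayModel] = None,
    rules: Optional[list[RewriteRule]] = None,
    policy: SubjectUriPolicy = DEFAULT_POLICY,
) -> Graph:
    """Only the produced WP-layer triples (no GPML-layer union)."""
    if rules is None:
        if model is None:
            raise ValueError("procedural engine needs the pathway model")
        return _procedural_wp_triples(model, policy)
    out = Graph()
    for prefix, base in PREFIXES.items():
        out.bind(prefix, base)
    for rule in rules:
        for triple in rule.apply(gpml_graph):
            out.add(triple)
    return out


# --- reverse direction: WP graph back to a renderable pathway model ---------

#: WP class -> GPML node category (non-injective inverse of NODE_TYPE_MAP).
REVERSE_NODE_TYPE = {
    WP.GeneProduct: NodeType.GeneProduct,
    WP.Protein: NodeType.Protein,
    WP.Rna: NodeType.Rna,
    WP.Metabolite: NodeType.Metabolite,
    WP.Pathway: NodeType.Pathway,
    WP.Complex: NodeType.Complex,
    WP.DataNode: NodeType.Unknown,
}

REVERSE_ARROW = {
    WP.DirectedInteraction: ArrowHead("Arrow"),
    WP.Inhibition: ArrowHead("TBar"),
    WP.Conversion: ArrowHead("MimConversion"),
    WP.Catalysis: ArrowHead("MimCatalysis"),
    WP.Interaction: ArrowHead("Line"),
}

INTERACTION_CLASSES = set(REVERSE_ARROW)

#: identifiers.org namespace path -> inferred node category, used when a
#: member entity carries no WP class triple (e.g. a bare membership graph).
_NAMESPACE_TYPES = {
    "chebi": NodeType.Metabolite,
    "hmdb": NodeType.Metabolite,
    "chemspider": NodeType.Metabolite,
    "pubchem.compound": NodeType.Metabolite,
    "kegg.compound": NodeType.Metabolite,
    "ncbigene": NodeType.GeneProduct,
    "ensembl": NodeType.GeneProduct,
    "uniprot": NodeType.Protein,
    "wikipathways": NodeType.Pathway,
}


@dataclass(frozen=True)
class LayoutDefaults:
    """Deterministic grid layout for reconstructed diagrams (diagram units)."""

    origin_x: float = 100.0
    origin_y: float = 100.0
    dx: float = 150.0
    dy: float = 80.0
    columns: int = 8
    node_width: float = 90.0
    node_height: float = 25.0


class ReverseConversionError(ValueError):
    pass


def _infer_node_type(graph: Graph, subject) -> NodeType:
    for cls in graph.objects(subject, RDF.type):
        if cls in REVERSE_NODE_TYPE:
            return REVERSE_NODE_TYPE[cls]
    m = re.match(r"http://identifiers\.org/([^/]+)/", str(subject))
    if m:
        return _NAMESPACE_TYPES.get(m.group(1), NodeType.Unknown)
    return NodeType.Unknown


def reverse_to_gpml(
    wp_graph: Graph, layout_defaults: LayoutDefaults = LayoutDefaults()
) -> PathwayModel:
    """Reconstruct a renderable pathway model from a WP-layer graph.

    The pathway subject is the wp:Pathway-typed subject that is not itself
    part of another pathway (falling back to any subject with skos:member,
    so bare membership graphs convert too).  Data nodes come from
    membership/containment triples, typed by WP class when present and by
    identifiers.org namespace otherwise; interactions from wp:source /
    wp:target pairs.  Coordinates are assigned on a deterministic grid.
    """
    member_subjects = set(wp_graph.subjects(SKOS.member, None))
    typed_pathways = set(wp_graph.subjects(RDF.type, WP.Pathway))
    contained = {s for s in typed_pathways if (s, DCTERMS.isPartOf, None) in wp_graph}
    candidates = sorted((typed_pathways - contained) | member_subjects)
    if not candidates:
        raise ReverseConversionError("graph contains no pathway subject")
    pw = candidates[0]

    wp_id_match = re.search(r"(WP\d+)", str(pw))
    title = ""
    for o in wp_graph.objects(pw, DC.title):
        title = str(o)
        break
    if not title:
        for o in wp_graph.objects(pw, RDFS.label):
            title = str(o)
            break

    organism_name = ""
    for o in wp_graph.objects(pw, WP.organismName):
        organism_name = str(o)
        break
    taxon_uri = None
    for o in wp_graph.objects(pw, WP.organism):
        taxon_uri = str(o)
        break

    model = PathwayModel(
        wp_id=wp_id_match.group(1) if wp_id_match else "WP0",
        title=title,
        organism_name=organism_name,
        organism_taxon_uri=taxon_uri,
        source_file="reverse_to_gpml",
    )

    entity_subjects = set(wp_graph.objects(pw, SKOS.member))
    for s in wp_graph.subjects(DCTERMS.isPartOf, pw):
        classes = set(wp_graph.objects(s, RDF.type))
        if classes & INTERACTION_CLASSES and not classes & set(REVERSE_NODE_TYPE):
            continue
        if (s, WP.source, None) in wp_graph or (s, WP.target, None) in wp_graph:
            continue
        entity_subjects.add(s)

    def existing_graph_id(s) -> Optional[str]:
        for o in wp_graph.objects(s, GPML.graphId):
            return str(o)
        return None

    layout = layout_defaults
    node_id_of: dict = {}
    for i, s in enumerate(sorted(entity_subjects)):
        gid = existing_graph_id(s) or f"n{i + 1:04d}"
        label = ""
        for o in wp_graph.objects(s, RDFS.label):
            label = str(o)
            break
        xref = None
        source = next(wp_graph.objects(s, DC.source), None)
        accession = next(wp_graph.objects(s, DCTERMS.identifier), None)
        if source is not None and accession is not None:
            xref = (str(source), str(accession))
        model.data_nodes.append(
            DataNode(
                graph_id=gid,
                text_label=label,
                node_type=_infer_node_type(wp_graph, s),
                center_x=layout.origin_x + layout.dx * (i % layout.columns),
                center_y=layout.origin_y + layout.dy * (i // layout.columns),
                width=layout.node_width,
                height=layout.node_height,
                xref=xref,
            )
        )
        node_id_of[s] = gid

    interaction_subjects = {
        s
        for s in wp_graph.subjects(RDF.type, None)
        if set(wp_graph.objects(s, RDF.type)) & INTERACTION_CLASSES
        and s not in entity_subjects
    }
    for j, s in enumerate(sorted(interaction_subjects)):
        classes = set(wp_graph.objects(s, RDF.type)) & INTERACTION_CLASSES
        arrow = REVERSE_ARROW[sorted(classes)[0]]
        source = next(wp_graph.objects(s, WP.source), None)
        target = next(wp_graph.objects(s, WP.target), None)
        gid = existing_graph_id(s) or f"e{j + 1:04d}"
        src_id = node_id_of.get(source)
        tgt_id = node_id_of.get(target)
        sx = sy = tx = ty = 0.0
        model.interactions.append(
            InteractionEdge(
                graph_id=gid,
                source_ref=src_id,
                target_ref=tgt_id,
                arrow_head=arrow,
                waypoints=[(sx, sy), (tx, ty)],
            )
        )
    return model
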