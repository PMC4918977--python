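"""Graphical-layer RDF: one-to-one serialization of a pathway model into
GPML-vocabulary triples.

Every markup element becomes a subject with its markup values as typed
literals — coordinates as xsd:float, z-order as xsd:integer, labels tagged
``@en``.  Subjects for annotated data nodes are their identifiers.org URIs
(so the glucose box in a glycolysis diagram is literally the ChEBI glucose
URI); everything else gets a pathway-local URI.  A consequence of the
identifiers.org policy is that two boxes annotated with the same accession
share one subject; their ``gpml:graphId`` triples keep the occurrences
distinguishable, and the ``pathway_local_always`` mode avoids the merge
entirely for lossless graphics work.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DC, RDF, RDFS, XSD

from .idmap import MintingError, mint_identifiers_org_uri
from .model import DataNode, NodeType, PathwayModel, validate
from .vocab import GPML, PREFIXES


class SubjectMode(enum.Enum):
    identifiers_org_when_xref = "identifiers_org_when_xref"
    pathway_local_always = "pathway_local_always"


@dataclass(frozen=True)
class SubjectUriPolicy:
    mode: SubjectMode = SubjectMode.identifiers_org_when_xref
    pathway_base: str = "http://rdf.wikipathways.org/Pathway/{wp_id}/{graph_id}"

    def __post_init__(self) -> None:
        if "{wp_id}" not in self.pathway_base or "{graph_id}" not in self.pathway_base:
            raise ValueError("pathway_base needs {wp_id} and {graph_id} slots")


DEFAULT_POLICY = SubjectUriPolicy()

PATHWAY_URI_TEMPLATE = "http://identifiers.org/wikipathways/{wp_id}"


def pathway_subject(model: PathwayModel) -> URIRef:
    return URIRef(PATHWAY_URI_TEMPLATE.format(wp_id=model.wp_id))


def local_subject(model: PathwayModel, graph_id: str, policy: SubjectUriPolicy) -> URIRef:
    return URIRef(policy.pathway_base.format(wp_id=model.wp_id, graph_id=graph_id))


def node_subject(model: PathwayModel, node: DataNode, policy: SubjectUriPolicy) -> URIRef:
    if (
        policy.mode is SubjectMode.identifiers_org_when_xref
        and node.xref is not None
    ):
        try:
            return mint_identifiers_org_uri(*node.xref)
        except MintingError:
            pass  # unregistered database: fall back to a local subject
    return local_subject(model, node.graph_id, policy)


def _new_graph() -> Graph:
    g = Graph()
    for prefix, base in PREFIXES.items():
        g.bind(prefix, base)
    return g


def emit_gpml_layer(model: PathwayModel, policy: SubjectUriPolicy = DEFAULT_POLICY) -> Graph:
    """Emit the GPML-vocabulary graph for one pathway model.

    The model must validate.  The triple set is a deterministic function of
    the model; per element:

    * pathway: ``rdf:type gpml:Pathway``, ``dc:title``, organism name/taxon
    * data node: type, ``rdfs:label``@en, graphId, ZOrder, centerX/Y,
      width/height, nodeType, containment, and — when annotated — the xref
      database, accession and identifiers.org URI
    * interaction: type, graphId, arrowhead, indexed waypoints, anchor ids,
      raw endpoint references plus resolved endpoint URIs
    * label: type, text, graphId, geometry, containment
    """
    problems = validate(model)
    if problems:
        details = "; ".join(f"{v.graph_id}: {v.rule}" for v in problems)
        raise ValueError(f"model does not validate: {details}")

    g = _new_graph()
    pw = pathway_subject(model)
    g.add((pw, RDF.type, GPML.Pathway))
    g.add((pw, DC.title, Literal(model.title)))
    if model.organism_name:
        g.add((pw, GPML.organismName, Literal(model.organism_name)))
    if model.organism_taxon_uri:
        g.add((pw, GPML.organism, URIRef(model.organism_taxon_uri)))

    subj_of: dict[str, URIRef] = {}
    for node in model.data_nodes:
        subj_of[node.graph_id] = node_subject(model, node, policy)
    for edge in model.interactions:
        uri = local_subject(model, edge.graph_id, policy)
        subj_of[edge.graph_id] = uri
        for anchor_id in edge.anchors:
            subj_of[anchor_id] = uri  # anchor refs resolve to the owning line

    for node in model.data_nodes:
        s = subj_of[node.graph_id]
        g.add((s, RDF.type, GPML.DataNode))
        g.add((s, RDFS.label, Literal(node.text_label, lang="en")))
        g.add((s, GPML.graphId, Literal(node.graph_id)))
        g.add((s, GPML.ZOrder, Literal(node.z_order, datatype=XSD.integer)))
        g.add((s, GPML.centerX, Literal(node.center_x, datatype=XSD.float)))
        g.add((s, GPML.centerY, Literal(node.center_y, datatype=XSD.float)))
        g.add((s, GPML.width, Literal(node.width, datatype=XSD.float)))
        g.add((s, GPML.height, Literal(node.height, datatype=XSD.float)))
        g.add((s, GPML.nodeType, Literal(node.node_type.value)))
        g.add((s, GPML.isPartOf, pw))
        if node.xref is not None:
            database, accession = node.xref
            g.add((s, GPML.xrefDataSource, Literal(database, datatype=XSD.string)))
            g.add((s, GPML.xrefId, Literal(accession)))
            try:
                g.add((s, GPML.xref, mint_identifiers_org_uri(database, accession)))
            except MintingError:
                pass

    for edge in model.interactions:
        s = subj_of[edge.graph_id]
        g.add((s, RDF.type, GPML.Interaction))
        g.add((s, GPML.graphId, Literal(edge.graph_id)))
        g.add((s, GPML.isPartOf, pw))
        g.add((s, GPML.arrowHead, Literal(edge.arrow_head.to_xml())))
        for i, (x, y) in enumerate(edge.waypoints):
            g.add((s, GPML.waypoint, Literal(f"{i}:{x!r},{y!r}")))
        for anchor_id in edge.anchors:
            g.add((s, GPML.anchor, Literal(anchor_id)))
        for prop_ref, prop_uri, ref in (
            (GPML.sourceRef, GPML.source, edge.source_ref),
            (GPML.targetRef, GPML.target, edge.target_ref),
        ):
            if ref is None:
                continue
            g.add((s, prop_ref, Literal(ref)))
            resolved = subj_of.get(ref)
            if resolved is not None and resolved != s:
                g.add((s, prop_uri, resolved))

    for lab in model.labels:
        s = local_subject(model, lab.graph_id, policy)
        g.add((s, RDF.type, GPML.Label))
        g.add((s, RDFS.label, Literal(lab.text_label, lang="en")))
        g.add((s, GPML.graphId, Literal(lab.graph_id)))
        g.add((s, GPML.centerX, Literal(lab.center_x, datatype=XSD.float)))
        g.add((s, GPML.centerY, Literal(lab.center_y, datatype=XSD.float)))
        g.add((s, GPML.width, Literal(lab.width, datatype=XSD.float)))
        g.add((s, GPML.height, Literal(lab.height, datatype=XSD.float)))
        g.add((s, GPML.isPartOf, pw))

    return g


def serialize(graph: Graph, format: str = "turtle") -> bytes:
    """Serialize to Turtle or (lexicographically sorted, byte-stable) N-Triples."""
    if format == "turtle":
        return graph.serialize(format="turtle", encoding="utf-8")
    if format == "ntriples":
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
        )
        return ("\n".join(lines) + ("\n" if lines else "")).encode("utf-8")
    raise ValueError(f"unknown serialization format {format!r} (use turtle or ntriples)")


def datanodes_from_gpml_graph(graph: Graph) -> list[DataNode]:
    """Reverse mapping: reconstruct DataNode records from a GPML-layer graph.

    Recovers every DataNode field (document order excluded).  Faithful
    per-occurrence reconstruction requires the ``pathway_local_always``
    subject policy, under which each box keeps its own subject.
    """
    nodes = []
    for s in sorted(set(graph.subjects(RDF.type, GPML.DataNode))):
        def one(pred, default=None):
            for o in graph.objects(s, pred):
                return o
            return default

        xref = None
        database = one(GPML.xrefDataSource)
        accession = one(GPML.xrefId)
        if database is not None and accession is not None:
            xref = (str(database), str(accession))
        nodes.append(
            DataNode(
                graph_id=str(one(GPML.graphId)),
                text_label=str(one(RDFS.label, Literal(""))),
                node_type=NodeType(str(one(GPML.nodeType, Literal("Unknown")))),
                center_x=float(one(GPML.centerX, Literal(0.0))),
                center_y=float(one(GPML.centerY, Literal(0.0))),
                width=float(one(GPML.width, Literal(0.0))),
                height=float(one(GPML.height, Literal(0.0))),
                z_order=int(one(GPML.ZOrder, Literal(32768))),
                xref=xref,
            )
        )
    return nodes
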