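"""Typed in-memory representation of a GPML pathway diagram, plus reader/writer.

GPML (Graphical Pathway Markup Language) is the XML dialect used by pathway
editors to store both the drawing (coordinates, z-order, widths) and the
biological annotation (Xref database + accession) of a pathway diagram.
Genes, proteins, RNAs, metabolites and links to other pathways are all
"DataNodes" rendered as boxes; interactions are lines with arrowheads; free
text is a Label.

The model here is deliberately lossy-free with respect to the fields the RDF
layers need: every DataNode keeps its graphics values exactly as parsed
(floats, diagram units, origin top-left with y growing downward) and its Xref
verbatim.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

log = logging.getLogger(__name__)

GPML_NS_2013 = "http://pathvisio.org/GPML/2013a"

#: Organism name -> NCBI taxon id, for the species WikiPathways curates most.
#: GPML stores only the organism *name*; the taxon URI is derived from this
#: table so that write->parse round-trips are exact.
SPECIES_TAXA: dict[str, int] = {
    "Homo sapiens": 9606,
    "Mus musculus": 10090,
    "Rattus norvegicus": 10116,
    "Danio rerio": 7955,
    "Drosophila melanogaster": 7227,
    "Caenorhabditis elegans": 6239,
    "Saccharomyces cerevisiae": 4932,
    "Arabidopsis thaliana": 3702,
    "Bos taurus": 9913,
    "Gallus gallus": 9031,
    "Canis familiaris": 9615,
    "Pan troglodytes": 9598,
    "Oryza sativa": 4530,
    "Escherichia coli": 562,
    "Sus scrofa": 9823,
}

TAXON_URI_TEMPLATE = "http://identifiers.org/taxonomy/{taxon}"


def taxon_uri_for_organism(name: Optional[str]) -> Optional[str]:
    if not name:
        return None
    taxon = SPECIES_TAXA.get(name)
    if taxon is None:
        return None
    return TAXON_URI_TEMPLATE.format(taxon=taxon)


class NodeType(enum.Enum):
    """Biological category of a DataNode, as declared by its Type attribute."""

    GeneProduct = "GeneProduct"
    Protein = "Protein"
    Rna = "Rna"
    Metabolite = "Metabolite"
    Pathway = "Pathway"
    Complex = "Complex"
    Unknown = "Unknown"


@dataclass(frozen=True)
class ArrowHead:
    """Arrowhead of an interaction end.

    Known kinds carry directed/undirected semantics downstream; anything else
    is preserved verbatim in ``other`` (never dropped — the rule layer decides
    what unknown decorations mean).
    """

    kind: str  # Line | Arrow | TBar | MimConversion | MimCatalysis | MimInhibition | Other
    other: Optional[str] = None

    KNOWN = ("Line", "Arrow", "TBar", "MimConversion", "MimCatalysis", "MimInhibition")

    #: GPML attribute spellings for the known kinds.
    _XML_NAMES = {
        "Line": "Line",
        "Arrow": "Arrow",
        "TBar": "TBar",
        "MimConversion": "mim-conversion",
        "MimCatalysis": "mim-catalysis",
        "MimInhibition": "mim-inhibition",
    }

    def __post_init__(self) -> None:
        if self.kind == "Other" and not self.other:
            raise ValueError("ArrowHead kind 'Other' requires the verbatim string")
        if self.kind != "Other" and self.kind not in self.KNOWN:
            raise ValueError(f"unknown ArrowHead kind {self.kind!r}")

    @classmethod
    def from_xml(cls, value: Optional[str]) -> "ArrowHead":
        if not value:
            return cls("Line")
        for kind, xml_name in cls._XML_NAMES.items():
            if value == xml_name or value == kind:
                return cls(kind)
        return cls("Other", other=value)

    def to_xml(self) -> str:
        if self.kind == "Other":
            return self.other  # type: ignore[return-value]
        return self._XML_NAMES[self.kind]


@dataclass
class DataNode:
    graph_id: str
    text_label: str
    node_type: NodeType = NodeType.Unknown
    center_x: float = 0.0
    center_y: float = 0.0
    width: float = 80.0
    height: float = 20.0
    z_order: int = 32768
    xref: Optional[tuple[str, str]] = None  # (database name, accession)


@dataclass
class InteractionEdge:
    graph_id: str
    source_ref: Optional[str] = None  # graph_id of start node, or anchor id
    target_ref: Optional[str] = None
    arrow_head: ArrowHead = field(default_factory=lambda: ArrowHead("Line"))
    anchors: list[str] = field(default_factory=list)
    waypoints: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FreeLabel:
    graph_id: str
    text_label: str
    center_x: float = 0.0
    center_y: float = 0.0
    width: float = 0.0
    height: float = 0.0


@dataclass
class PathwayModel:
    wp_id: str
    title: str = ""
    organism_name: str = ""
    organism_taxon_uri: Optional[str] = None
    data_nodes: list[DataNode] = field(default_factory=list)
    interactions: list[InteractionEdge] = field(default_factory=list)
    labels: list[FreeLabel] = field(default_factory=list)
    source_file: str = field(default="", compare=False)  # provenance only

    def element_ids(self) -> list[str]:
        return (
            [n.graph_id for n in self.data_nodes]
            + [i.graph_id for i in self.interactions]
            + [l.graph_id for l in self.labels]
        )

    def node_by_id(self) -> dict[str, DataNode]:
        return {n.graph_id: n for n in self.data_nodes}


@dataclass(frozen=True)
class Violation:
    graph_id: str
    rule: str
    message: str


class GpmlParseError(ValueError):
    pass


class GpmlValidationError(ValueError):
    pass


def _local(tag) -> str:
    """Namespace-free tag name; GPML has several dated namespaces."""
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _float(elem, attr: str, default: float = 0.0) -> float:
    raw = elem.get(attr)
    return float(raw) if raw is not None else default


_WP_ID_FALLBACK = "WP0"


def parse_gpml(xml_bytes: bytes, wp_id: Optional[str] = None) -> PathwayModel:
    """Parse GPML XML into a :class:`PathwayModel`.

    Accepts any GPML namespace (the dialect has several dated namespace URIs);
    the namespace found is recorded in ``source_file`` provenance.  The
    WikiPathways accession is taken from the ``wp_id`` argument if given, else
    from a ``WPID`` attribute on the Pathway element, else ``"WP0"`` (real
    GPML files carry the accession out-of-band).

    Elements without a GraphId get a synthesized deterministic id
    ``auto-NNNN`` (document order) with a warning.  Duplicate GraphIds are a
    hard error.  An Xref with an empty Database or ID attribute is treated as
    absent (with a warning).
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise GpmlParseError(f"malformed GPML XML: {exc}") from exc
    if _local(root.tag) != "Pathway":
        raise GpmlParseError(f"expected Pathway root element, got {_local(root.tag)!r}")

    namespace = root.tag.rsplit("}", 1)[0].lstrip("{") if "}" in root.tag else ""
    if wp_id is None:
        wp_id = root.get("WPID") or _WP_ID_FALLBACK

    organism = root.get("Organism", "") or ""
    model = PathwayModel(
        wp_id=wp_id,
        title=root.get("Name", "") or "",
        organism_name=organism,
        organism_taxon_uri=taxon_uri_for_organism(organism),
        source_file=f"namespace={namespace}" if namespace else "",
    )

    counter = 0
    seen: dict[str, str] = {}

    def take_id(elem, what: str) -> str:
        nonlocal counter
        counter += 1
        gid = elem.get("GraphId")
        if not gid:
            gid = f"auto-{counter:04d}"
            log.warning("%s element without GraphId: synthesized %s", what, gid)
        if gid in seen:
            raise GpmlParseError(
                f"duplicate GraphId {gid!r} on {what} (already used by {seen[gid]})"
            )
        seen[gid] = what
        return gid

    def find_child(elem, name: str):
        for child in elem:
            if _local(child.tag) == name:
                return child
        return None

    def parse_xref(elem) -> Optional[tuple[str, str]]:
        xref = find_child(elem, "Xref")
        if xref is None:
            return None
        database = xref.get("Database", "") or ""
        accession = xref.get("ID", "") or ""
        if not database or not accession:
            log.warning("Xref with empty Database/ID treated as absent")
            return None
        return (database, accession)

    for elem in root:
        tag = _local(elem.tag)
        if tag == "DataNode":
            gid = take_id(elem, "DataNode")
            graphics = find_child(elem, "Graphics")
            node = DataNode(
                graph_id=gid,
                text_label=elem.get("TextLabel", "") or "",
                node_type=_node_type(elem.get("Type")),
                xref=parse_xref(elem),
            )
            if graphics is not None:
                node.center_x = _float(graphics, "CenterX")
                node.center_y = _float(graphics, "CenterY")
                node.width = _float(graphics, "Width", 80.0)
                node.height = _float(graphics, "Height", 20.0)
                z = graphics.get("ZOrder")
                node.z_order = int(z) if z is not None else 32768
            model.data_nodes.append(node)
        elif tag == "Interaction":
            gid = take_id(elem, "Interaction")
            edge = InteractionEdge(graph_id=gid)
            graphics = find_child(elem, "Graphics")
            arrow = None
            if graphics is not None:
                points = [c for c in graphics if _local(c.tag) == "Point"]
                for point in points:
                    edge.waypoints.append((_float(point, "X"), _float(point, "Y")))
                    if point.get("ArrowHead"):
                        arrow = point.get("ArrowHead")
                if points:
                    edge.source_ref = points[0].get("GraphRef")
                    edge.target_ref = points[-1].get("GraphRef")
                for anchor in (c for c in graphics if _local(c.tag) == "Anchor"):
                    aid = anchor.get("GraphId")
                    if aid:
                        edge.anchors.append(aid)
            edge.arrow_head = ArrowHead.from_xml(arrow)
            if len(edge.waypoints) < 2:
                # a line needs two ends to be drawable; pad degenerate input
                while len(edge.waypoints) < 2:
                    edge.waypoints.append((0.0, 0.0))
                log.warning("Interaction %s has fewer than 2 points; padded", gid)
            model.interactions.append(edge)
        elif tag == "Label":
            gid = take_id(elem, "Label")
            graphics = find_child(elem, "Graphics")
            lab = FreeLabel(graph_id=gid, text_label=elem.get("TextLabel", "") or "")
            if graphics is not None:
                lab.center_x = _float(graphics, "CenterX")
                lab.center_y = _float(graphics, "CenterY")
                lab.width = _float(graphics, "Width")
                lab.height = _float(graphics, "Height")
            model.labels.append(lab)

    return model


def _node_type(raw: Optional[str]) -> NodeType:
    if not raw:
        return NodeType.Unknown
    try:
        return NodeType(raw)
    except ValueError:
        return NodeType.Unknown


def _fmt(value: float) -> str:
    return repr(float(value))


def write_gpml(model: PathwayModel) -> bytes:
    """Serialize a PathwayModel to GPML XML (UTF-8).

    ``parse_gpml(write_gpml(m))`` equals ``m`` field for field.  Raises
    :class:`GpmlValidationError` if the model violates its invariants.
    """
    problems = validate(model)
    if problems:
        details = "; ".join(f"{v.graph_id}: {v.rule}" for v in problems)
        raise GpmlValidationError(f"model violates invariants: {details}")

    root = etree.Element("{%s}Pathway" % GPML_NS_2013, nsmap={None: GPML_NS_2013})
    root.set("Name", model.title)
    if model.organism_name:
        root.set("Organism", model.organism_name)
    root.set("WPID", model.wp_id)

    def graphics(parent, **attrs):
        g = etree.SubElement(parent, "{%s}Graphics" % GPML_NS_2013)
        for key, value in attrs.items():
            g.set(key, value)
        return g

    for node in model.data_nodes:
        e = etree.SubElement(root, "{%s}DataNode" % GPML_NS_2013)
        e.set("TextLabel", node.text_label)
        e.set("GraphId", node.graph_id)
        e.set("Type", node.node_type.value)
        graphics(
            e,
            CenterX=_fmt(node.center_x),
            CenterY=_fmt(node.center_y),
            Width=_fmt(node.width),
            Height=_fmt(node.height),
            ZOrder=str(node.z_order),
        )
        if node.xref is not None:
            x = etree.SubElement(e, "{%s}Xref" % GPML_NS_2013)
            x.set("Database", node.xref[0])
            x.set("ID", node.xref[1])

    for edge in model.interactions:
        e = etree.SubElement(root, "{%s}Interaction" % GPML_NS_2013)
        e.set("GraphId", edge.graph_id)
        g = graphics(e)
        last = len(edge.waypoints) - 1
        for i, (x, y) in enumerate(edge.waypoints):
            p = etree.SubElement(g, "{%s}Point" % GPML_NS_2013)
            p.set("X", _fmt(x))
            p.set("Y", _fmt(y))
            if i == 0 and edge.source_ref:
                p.set("GraphRef", edge.source_ref)
            if i == last and edge.target_ref:
                p.set("GraphRef", edge.target_ref)
            if i == last and edge.arrow_head.kind != "Line":
                p.set("ArrowHead", edge.arrow_head.to_xml())
        for aid in edge.anchors:
            a = etree.SubElement(g, "{%s}Anchor" % GPML_NS_2013)
            a.set("GraphId", aid)

    for lab in model.labels:
        e = etree.SubElement(root, "{%s}Label" % GPML_NS_2013)
        e.set("TextLabel", lab.text_label)
        e.set("GraphId", lab.graph_id)
        graphics(
            e,
            CenterX=_fmt(lab.center_x),
            CenterY=_fmt(lab.center_y),
            Width=_fmt(lab.width),
            Height=_fmt(lab.height),
        )

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


_WP_ID_RE = re.compile(r"^WP\d+$")


def validate(model: PathwayModel) -> list[Violation]:
    """Check the model invariants; returns one record per violation, never raises."""
    violations: list[Violation] = []
    if not _WP_ID_RE.match(model.wp_id):
        violations.append(
            Violation(model.wp_id, "wp_id-pattern", "wp_id must match WP<digits>")
        )

    seen: dict[str, str] = {}
    for kind, elems in (
        ("DataNode", model.data_nodes),
        ("Interaction", model.interactions),
        ("Label", model.labels),
    ):
        for elem in elems:
            gid = elem.graph_id
            if gid in seen:
                violations.append(
                    Violation(
                        gid,
                        "duplicate-graph-id",
                        f"graph_id used by both {seen[gid]} and {kind} {gid}",
                    )
                )
            else:
                seen[gid] = f"{kind} {gid}"

    for node in model.data_nodes:
        if not (node.width > 0 and node.height > 0):
            violations.append(
                Violation(node.graph_id, "positive-extent", "width/height must be > 0")
            )
    for lab in model.labels:
        if lab.width < 0 or lab.height < 0:
            violations.append(
                Violation(lab.graph_id, "nonnegative-extent", "width/height must be >= 0")
            )

    anchor_ids = {aid for edge in model.interactions for aid in edge.anchors}
    referable = set(seen) | anchor_ids
    for edge in model.interactions:
        if len(edge.waypoints) < 2:
            violations.append(
                Violation(edge.graph_id, "waypoints", "needs at least 2 waypoints")
            )
        for role, ref in (("source_ref", edge.source_ref), ("target_ref", edge.target_ref)):
            if ref is not None and ref not in referable:
                violations.append(
                    Violation(
                        edge.graph_id,
                        "dangling-ref",
                        f"{role} {ref!r} does not resolve to any graph_id or anchor",
                    )
                )
    return violations
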