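"""Unified-identifier mapping.

Query writers should not have to know which database a curator happened to
annotate a node with.  Instead of a live mapping service, every annotated
entity is mapped ahead of time to a small set of canonical identifier
systems — Entrez Gene, Ensembl and UniProt for gene products; HMDB and
ChemSpider for compounds — and the mappings are materialised as partially
redundant ``wp:bdb*`` triples next to the original annotation.  The original
curator-provided identifier is always kept as a ``dc:identifier`` triple
whose object is the identifiers.org URI.

The mapping table itself is a 4-column TSV (source_system, source_id,
unified_system, unified_id), standing in for a BridgeDb-style mapping
database; it may be many-to-many.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml
from rdflib import Graph, URIRef
from rdflib.namespace import DC

from .model import NodeType, PathwayModel
from .vocab import PREFIXES, WP, term

log = logging.getLogger(__name__)


class UnifiedSystem(enum.Enum):
    EntrezGene = "EntrezGene"
    Ensembl = "Ensembl"
    UniProt = "UniProt"
    HMDB = "HMDB"
    ChemSpider = "ChemSpider"


#: wp:bdb* predicate for each unified system.
BDB_PREDICATES: dict[UnifiedSystem, URIRef] = {
    UnifiedSystem.EntrezGene: WP.bdbEntrezGene,
    UnifiedSystem.Ensembl: WP.bdbEnsembl,
    UnifiedSystem.UniProt: WP.bdbUniprot,
    UnifiedSystem.HMDB: WP.bdbHmdb,
    UnifiedSystem.ChemSpider: WP.bdbChemspider,
}

#: Xref database names that *are* one of the unified systems (for
#: self-mapping: an Ensembl-annotated node gets wp:bdbEnsembl to itself).
SYSTEM_SYNONYMS: dict[str, UnifiedSystem] = {
    "Entrez Gene": UnifiedSystem.EntrezGene,
    "EntrezGene": UnifiedSystem.EntrezGene,
    "NCBI Gene": UnifiedSystem.EntrezGene,
    "Ensembl": UnifiedSystem.Ensembl,
    "UniProt": UnifiedSystem.UniProt,
    "Uniprot-TrEMBL": UnifiedSystem.UniProt,
    "Uniprot-SwissProt": UnifiedSystem.UniProt,
    "HMDB": UnifiedSystem.HMDB,
    "ChemSpider": UnifiedSystem.ChemSpider,
}


class MintingError(KeyError):
    pass


def _load_uri_templates() -> dict[str, str]:
    text = resources.files("gpml2rdf.data").joinpath("uri_templates.yaml").read_text()
    return yaml.safe_load(text)


#: system name -> identifiers.org URI template with an {id} slot.
URI_TEMPLATES: dict[str, str] = _load_uri_templates()


def mint_identifiers_org_uri(
    system: str, accession: str, templates: Optional[dict[str, str]] = None
) -> URIRef:
    """Deterministic identifiers.org URI for a (database, accession) pair.

    >>> str(mint_identifiers_org_uri("ChEBI", "CHEBI:4167"))
    'http://identifiers.org/chebi/CHEBI:4167'
    """
    table = URI_TEMPLATES if templates is None else templates
    template = table.get(system)
    if template is None:
        raise MintingError(f"no identifiers.org URI template registered for {system!r}")
    return URIRef(template.format(id=accession))


class MappingLoadError(ValueError):
    pass


@dataclass
class IdentifierMap:
    """Many-to-many (source_system, source_id) -> {(unified_system, unified_id)}."""

    records: set[tuple[str, str, UnifiedSystem, str]] = field(default_factory=set)

    def add(self, source_system: str, source_id: str, unified: UnifiedSystem, unified_id: str) -> None:
        self.records.add((source_system, source_id, unified, unified_id))

    def lookup(self, source_system: str, source_id: str) -> set[tuple[UnifiedSystem, str]]:
        return {
            (usys, uid)
            for (ssys, sid, usys, uid) in self.records
            if ssys == source_system and sid == source_id
        }

    def __len__(self) -> int:
        return len(self.records)


def load_mapping_tsv(text: str) -> IdentifierMap:
    """Parse the 4-column mapping TSV ('#' starts a comment line); duplicates collapse."""
    idmap = IdentifierMap()
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise MappingLoadError(
                f"mapping TSV line {lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        ssys, sid, usys_raw, uid = (p.strip() for p in parts)
        try:
            usys = UnifiedSystem(usys_raw)
        except ValueError:
            raise MappingLoadError(
                f"mapping TSV line {lineno}: unknown unified system {usys_raw!r}"
            ) from None
        idmap.add(ssys, sid, usys, uid)
    return idmap


GENE_TYPES = frozenset({NodeType.GeneProduct, NodeType.Protein, NodeType.Rna})
COMPOUND_TYPES = frozenset({NodeType.Metabolite})

GENE_TARGETS = frozenset({UnifiedSystem.EntrezGene, UnifiedSystem.Ensembl, UnifiedSystem.UniProt})
COMPOUND_TARGETS = frozenset({UnifiedSystem.HMDB, UnifiedSystem.ChemSpider})


@dataclass(frozen=True)
class UnificationPolicy:
    """Routes node classes to unified-identifier target systems.

    Gene-type nodes (gene products, proteins, RNAs) only ever receive
    Entrez Gene / Ensembl / UniProt triples; metabolites only HMDB /
    ChemSpider.  Other node types receive no wp:bdb* triples.
    """

    gene_targets: frozenset = GENE_TARGETS
    compound_targets: frozenset = COMPOUND_TARGETS

    def targets_for(self, node_type: NodeType) -> frozenset:
        if node_type in GENE_TYPES:
            return self.gene_targets
        if node_type in COMPOUND_TYPES:
            return self.compound_targets
        return frozenset()


DEFAULT_POLICY = UnificationPolicy()


def unified_ids_for_node(
    node_type: NodeType,
    xref: tuple[str, str],
    idmap: IdentifierMap,
    policy: UnificationPolicy = DEFAULT_POLICY,
) -> set[tuple[UnifiedSystem, str]]:
    """Policy-filtered unified identifiers for one annotated node (incl. self-mapping)."""
    system, accession = xref
    found = set(idmap.lookup(system, accession))
    self_system = SYSTEM_SYNONYMS.get(system)
    if self_system is not None:
        found.add((self_system, accession))
    allowed = policy.targets_for(node_type)
    return {(usys, uid) for (usys, uid) in found if usys in allowed}


def emit_unified_triples(
    model: PathwayModel,
    idmap: IdentifierMap,
    policy: UnificationPolicy = DEFAULT_POLICY,
    subject_for=None,
) -> Graph:
    """wp:bdb* + dc:identifier triples for every xref-annotated node.

    ``subject_for(node) -> URIRef`` chooses the node subject; by default the
    identifiers.org URI of the node's own xref (matching the subject policy
    of the graphical layer).
    """
    from .gpml_layer import DEFAULT_POLICY as SUBJECT_POLICY, node_subject

    if subject_for is None:
        subject_for = lambda node: node_subject(model, node, SUBJECT_POLICY)

    g = Graph()
    for prefix, base in PREFIXES.items():
        g.bind(prefix, base)
    for node in model.data_nodes:
        if node.xref is None:
            continue
        subject = subject_for(node)
        try:
            original = mint_identifiers_org_uri(*node.xref)
        except MintingError:
            log.info("no URI template for xref system %r; skipping node %s",
                     node.xref[0], node.graph_id)
            continue
        g.add((subject, DC.identifier, original))
        unified = unified_ids_for_node(node.node_type, node.xref, idmap, policy)
        if not unified and idmap.lookup(*node.xref) == set():
            log.info("xref %r has no mapping rows", node.xref)
        for usys, uid in unified:
            g.add((subject, BDB_PREDICATES[usys], mint_identifiers_org_uri(usys.value, uid)))
    return g
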