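"""Deterministic synthetic-GPML corpus generator and in-paper fixtures.

The generator emulates the structure of a curated pathway collection — on
the order of a thousand diagrams across more than a dozen species, each a
few dozen boxes annotated with database cross-references and connected by
arrowheaded lines — at configurable scale, with a ground-truth manifest
(species, node lists with types and xrefs, edge lists, mapping rows)
written *before* any XML is rendered.  The manifest is the single oracle
for every count-based check downstream, which keeps those checks
non-circular.

Two literature fixtures are shipped verbatim: the ``glucose_node`` GPML
document embedding the canonical Glucose metabolite DataNode (graph id
``dba83``, ChEBI CHEBI:4167, box at 279.0/468.0, 112.0x20.0, z-order
32768) inside a WP534 glycolysis pathway, and the ``wp534_intro``
three-statement membership graph (glycolysis ``skos:member`` glucose, plus
the two English labels).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDFS, SKOS

from .model import SPECIES_TAXA, TAXON_URI_TEMPLATE

GLUCOSE_PATHWAY_TITLE = "Glycolysis and Gluconeogenesis (Homo sapiens)"

#: Minimal valid GPML document embedding the canonical Glucose DataNode with
#: its printed attribute values, inside pathway WP534.
GLUCOSE_NODE_GPML = f"""\
<?xml version="1.0" encoding="UTF-8"?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a"
         Name="{GLUCOSE_PATHWAY_TITLE}"
         Organism="Homo sapiens" WPID="WP534">
  <DataNode TextLabel="Glucose" GraphId="dba83" Type="Metabolite">
    <Graphics CenterX="279.0" CenterY="468.0" Width="112.0" Height="20.0" ZOrder="32768"/>
    <Xref Database="ChEBI" ID="CHEBI:4167"/>
  </DataNode>
</Pathway>
""".encode()


def _wp534_intro_graph() -> Graph:
    g = Graph()
    g.bind("skos", SKOS)
    g.bind("rdfs", RDFS)
    wp534 = URIRef("http://identifiers.org/wikipathways/WP534")
    glucose = URIRef("http://identifiers.org/chebi/CHEBI:4167")
    g.add((wp534, SKOS.member, glucose))
    g.add((wp534, RDFS.label, Literal(GLUCOSE_PATHWAY_TITLE, lang="en")))
    g.add((glucose, RDFS.label, Literal("Glucose", lang="en")))
    return g


def paper_fixture(name: str):
    """Return a shipped literature fixture by name.

    ``glucose_node`` -> GPML bytes; ``wp534_intro`` -> rdflib Graph with the
    three introduction statements.
    """
    if name == "glucose_node":
        return GLUCOSE_NODE_GPML
    if name == "wp534_intro":
        return _wp534_intro_graph()
    raise KeyError(f"unknown fixture {name!r} (use glucose_node or wp534_intro)")


# --- synthetic corpus -------------------------------------------------------

DEFAULT_SPECIES_POOL: list[tuple[str, str]] = [
    (name, TAXON_URI_TEMPLATE.format(taxon=taxon)) for name, taxon in SPECIES_TAXA.items()
]

#: Node-type mix loosely following a curated collection: mostly gene
#: products and proteins, a solid metabolite fraction, few RNAs, complexes
#: and pathway links.
DEFAULT_NODE_TYPE_WEIGHTS: dict[str, float] = {
    "GeneProduct": 0.40,
    "Protein": 0.18,
    "Metabolite": 0.22,
    "Rna": 0.05,
    "Pathway": 0.05,
    "Complex": 0.05,
    "Unknown": 0.05,
}

#: Annotation databases per node category (weighted).
DEFAULT_XREF_SYSTEMS: dict[str, list[tuple[str, float]]] = {
    "GeneProduct": [("Entrez Gene", 0.5), ("Ensembl", 0.5)],
    "Rna": [("Ensembl", 1.0)],
    "Protein": [("UniProt", 0.6), ("Ensembl", 0.4)],
    "Metabolite": [
        ("ChEBI", 0.3), ("HMDB", 0.3), ("ChemSpider", 0.2), ("PubChem-compound", 0.2),
    ],
    "Pathway": [("WikiPathways", 1.0)],
    "Complex": [],
    "Unknown": [],
}

DEFAULT_ARROWHEAD_WEIGHTS: dict[str, float] = {
    "Arrow": 0.45,
    "Line": 0.20,
    "TBar": 0.10,
    "mim-conversion": 0.12,
    "mim-catalysis": 0.08,
    "mim-inhibition": 0.05,
}

#: How many unified identifiers a single xref maps to (fan-out).
DEFAULT_MAPPING_FANOUT: dict[int, float] = {0: 0.15, 1: 0.55, 2: 0.25, 3: 0.05}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_pathways: int = 10
    species_pool: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_SPECIES_POOL)
    )
    nodes_per_pathway: tuple[int, int] = (6, 18)
    node_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NODE_TYPE_WEIGHTS)
    )
    xref_systems: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_XREF_SYSTEMS.items()}
    )
    xref_rate: float = 0.85
    edge_density: float = 0.08
    arrowhead_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARROWHEAD_WEIGHTS)
    )
    mapping_fanout: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MAPPING_FANOUT)
    )

    def validate(self) -> None:
        for name, dist in (
            ("node_type_weights", self.node_type_weights),
            ("arrowhead_weights", self.arrowhead_weights),
            ("mapping_fanout", self.mapping_fanout),
        ):
            if any(w < 0 for w in dist.values()):
                raise ValueError(f"{name}: weights must be nonnegative")
            if sum(dist.values()) <= 0:
                raise ValueError(f"{name}: weights must not all be zero")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be >= 0")
        lo, hi = self.nodes_per_pathway
        if not (0 < lo <= hi):
            raise ValueError("nodes_per_pathway must be a positive (low, high) range")


_UNIFIED_FOR_TYPE = {
    "GeneProduct": ["EntrezGene", "Ensembl", "UniProt"],
    "Protein": ["EntrezGene", "Ensembl", "UniProt"],
    "Rna": ["EntrezGene", "Ensembl", "UniProt"],
    "Metabolite": ["HMDB", "ChemSpider"],
}

_METABOLITE_NAMES = [
    "Glucose", "Pyruvate", "Lactate", "Citrate", "ATP", "NADH", "Acetyl-CoA",
    "Glutamate", "Serine", "Fumarate", "Malate", "Succinate",
]


def _weighted_choice(rng: random.Random, weights: dict) -> object:
    keys = list(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _synth_accession(rng: random.Random, system: str, serial: int) -> str:
    n = rng.randrange(10_000, 99_999)
    return {
        "Entrez Gene": f"{n}",
        "Ensembl": f"ENSG{serial:08d}{n % 100:02d}",
        "UniProt": f"P{n:05d}",
        "ChEBI": f"CHEBI:{n}",
        "HMDB": f"HMDB{n:07d}",
        "ChemSpider": f"{n}",
        "PubChem-compound": f"{n}",
        "WikiPathways": f"WP{900 + serial}",
    }.get(system, f"X{n}")


def _unified_accession(rng: random.Random, system: str) -> str:
    n = rng.randrange(10_000, 99_999)
    return {
        "EntrezGene": f"{n}",
        "Ensembl": f"ENSG{n:011d}",
        "UniProt": f"Q{n:05d}",
        "HMDB": f"HMDB{n:07d}",
        "ChemSpider": f"{n}",
    }[system]


def generate_corpus(config: GeneratorConfig) -> tuple[list[bytes], str, dict]:
    """Generate (GPML byte streams, mapping TSV text, ground-truth manifest).

    Identical seed + config give byte-identical output.  Every generated
    file validates with zero violations, and xref accessions are unique
    within a pathway so each box keeps a distinct RDF subject.
    """
    config.validate()
    rng = random.Random(config.seed)
    files: list[bytes] = []
    mapping_rows: list[tuple[str, str, str, str]] = []
    manifest: dict = {"seed": config.seed, "pathways": []}

    serial = 0
    for p in range(config.n_pathways):
        wp_id = f"WP{1000 + p}"
        species_name, taxon_uri = rng.choice(config.species_pool)
        n_nodes = rng.randint(*config.nodes_per_pathway)
        nodes = []
        used_accessions: set[tuple[str, str]] = set()
        for i in range(n_nodes):
            serial += 1
            node_type = _weighted_choice(rng, config.node_type_weights)
            graph_id = f"n{rng.randrange(16**5):05x}"
            while any(n["graph_id"] == graph_id for n in nodes):
                graph_id = f"n{rng.randrange(16**5):05x}"
            if node_type == "Metabolite":
                label = f"{rng.choice(_METABOLITE_NAMES)}-{serial}"
            elif node_type == "Pathway":
                label = f"linked pathway {serial}"
            else:
                label = f"GENE{serial}"
            xref = None
            systems = config.xref_systems.get(node_type, [])
            if systems and rng.random() < config.xref_rate:
                system = rng.choices(
                    [s for s, _ in systems], weights=[w for _, w in systems], k=1
                )[0]
                accession = _synth_accession(rng, system, serial)
                while (system, accession) in used_accessions:
                    accession = _synth_accession(rng, system, serial)
                used_accessions.add((system, accession))
                xref = [system, accession]
            nodes.append(
                {
                    "graph_id": graph_id,
                    "label": label,
                    "type": node_type,
                    "xref": xref,
                }
            )

        edges = []
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() >= config.edge_density:
                    continue
                src, tgt = (i, j) if rng.random() < 0.5 else (j, i)
                edges.append(
                    {
                        "graph_id": f"e{len(edges):04d}x{p}",
                        "source": nodes[src]["graph_id"],
                        "target": nodes[tgt]["graph_id"],
                        "arrow_head": _weighted_choice(rng, config.arrowhead_weights),
                    }
                )

        pw_mapping: list[list[str]] = []
        for node in nodes:
            if node["xref"] is None:
                continue
            targets = _UNIFIED_FOR_TYPE.get(node["type"])
            if not targets:
                continue
            fanout = _weighted_choice(rng, config.mapping_fanout)
            chosen = rng.sample(targets, k=min(fanout, len(targets)))
            for usys in sorted(chosen):
                uid = _unified_accession(rng, usys)
                row = (node["xref"][0], node["xref"][1], usys, uid)
                mapping_rows.append(row)
                pw_mapping.append(list(row))

        manifest["pathways"].append(
            {
                "wp_id": wp_id,
                "title": f"Synthetic pathway {wp_id} ({species_name})",
                "organism": species_name,
                "taxon_uri": taxon_uri,
                "nodes": nodes,
                "edges": edges,
                "mapping_rows": pw_mapping,
            }
        )
        files.append(_render_gpml(manifest["pathways"][-1]))

    tsv_lines = ["# source_system\tsource_id\tunified_system\tunified_id"]
    for row in sorted(set(mapping_rows)):
        tsv_lines.append("\t".join(row))
    mapping_tsv = "\n".join(tsv_lines) + "\n"
    return files, mapping_tsv, manifest


def _render_gpml(pw: dict) -> bytes:
    """Render one manifest pathway entry to GPML via the model writer."""
    from .model import (
        ArrowHead,
        DataNode,
        FreeLabel,
        InteractionEdge,
        NodeType,
        PathwayModel,
        write_gpml,
    )

    model = PathwayModel(
        wp_id=pw["wp_id"],
        title=pw["title"],
        organism_name=pw["organism"],
        organism_taxon_uri=pw["taxon_uri"],
    )
    for i, node in enumerate(pw["nodes"]):
        model.data_nodes.append(
            DataNode(
                graph_id=node["graph_id"],
                text_label=node["label"],
                node_type=NodeType(node["type"]),
                center_x=100.0 + 150.0 * (i % 8),
                center_y=100.0 + 80.0 * (i // 8),
                width=90.0,
                height=25.0,
                xref=tuple(node["xref"]) if node["xref"] else None,
            )
        )
    centers = {n.graph_id: (n.center_x, n.center_y) for n in model.data_nodes}
    for edge in pw["edges"]:
        model.interactions.append(
            InteractionEdge(
                graph_id=edge["graph_id"],
                source_ref=edge["source"],
                target_ref=edge["target"],
                arrow_head=ArrowHead.from_xml(edge["arrow_head"]),
                waypoints=[centers[edge["source"]], centers[edge["target"]]],
            )
        )
    model.labels.append(
        FreeLabel(
            graph_id=f"lab{pw['wp_id']}",
            text_label=pw["title"],
            center_x=300.0,
            center_y=30.0,
            width=400.0,
            height=25.0,
        )
    )
    return write_gpml(model)


def manifest_to_yaml(manifest: dict) -> str:
    return yaml.safe_dump(manifest, sort_keys=False)


def manifest_from_yaml(text: str) -> dict:
    return yaml.safe_load(text)
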