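"""VoID dataset-description headers.

Published RDF needs machine-readable provenance: what the dataset is, how
big it is, what license covers it.  The converted pathway triples are
covered by the Creative Commons Attribution 3.0 Unported license, and that
is stated in a VoID (Vocabulary of Interlinked Datasets) header generated by
the same code that generates the data — so the triple count can never drift
from the described graph.  The header is kept as a separate graph (written
to a ``.void.ttl`` file next to the data), never mixed into the data graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, RDF, XSD

from .vocab import PREFIXES, VOID

CC_BY_3_0 = "https://creativecommons.org/licenses/by/3.0/"


@dataclass
class DatasetDescriptor:
    dataset_uri: str
    title: str
    license_uri: str = CC_BY_3_0
    created: Optional[datetime] = None  # injectable for reproducible builds
    subset_uris: list[str] = field(default_factory=list)
    triple_count: Optional[int] = None  # computed by build_void, not pre-set


def build_void(graph: Graph, descriptor: DatasetDescriptor) -> Graph:
    """VoID header triples describing ``graph``.

    The triple count is computed here from the described graph's actual
    cardinality; a pre-set count is rejected so the invariant cannot be
    silently violated.
    """
    if descriptor.triple_count is not None:
        raise ValueError("triple_count is computed by build_void; do not pre-set it")
    descriptor.triple_count = len(graph)
    if descriptor.created is None:
        descriptor.created = datetime.now(timezone.utc)

    void = Graph()
    for prefix, base in PREFIXES.items():
        void.bind(prefix, base)
    ds = URIRef(descriptor.dataset_uri)
    void.add((ds, RDF.type, VOID.Dataset))
    void.add((ds, DCTERMS.title, Literal(descriptor.title)))
    void.add((ds, DCTERMS.license, URIRef(descriptor.license_uri)))
    void.add(
        (ds, DCTERMS.created, Literal(descriptor.created.isoformat(), datatype=XSD.dateTime))
    )
    void.add((ds, VOID.triples, Literal(descriptor.triple_count, datatype=XSD.integer)))
    for subset in descriptor.subset_uris:
        sub = URIRef(subset)
        void.add((ds, VOID.subset, sub))
        void.add((sub, RDF.type, VOID.Dataset))
    return void
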