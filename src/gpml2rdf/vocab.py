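"""Registry of the two pathway vocabularies and reused external terms.

Two vocabularies carry the converted pathways:

* ``gpml:`` — the graphical layer, mirroring GPML markup elements (DataNode,
  Interaction, graphId, ZOrder, coordinates) one-to-one as RDF classes and
  properties.
* ``wp:`` — the biological layer (Pathway, GeneProduct, Metabolite, directed
  interactions, organism, the ``wp:bdb*`` unified-identifier predicates),
  disregarding layout.

External terms (rdf/rdfs/skos/dc/dcterms/xsd/void/foaf) are registered here
too, so that every predicate any emitter in this package uses resolves
through one registry.  Alignment of wp terms to external ontologies (BioPAX)
uses graded SKOS similarity links (skos:exactMatch / skos:closeMatch).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DC, DCTERMS, OWL, RDF, RDFS, SKOS, XSD

GPML_BASE = "http://vocabularies.wikipathways.org/gpml#"
WP_BASE = "http://vocabularies.wikipathways.org/wp#"
VOID_BASE = "http://rdfs.org/ns/void#"
BIOPAX_BASE = "http://www.biopax.org/release/biopax-level3.owl#"

GPML = Namespace(GPML_BASE)
WP = Namespace(WP_BASE)
VOID = Namespace(VOID_BASE)

PREFIXES: dict[str, str] = {
    "gpml": GPML_BASE,
    "wp": WP_BASE,
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "skos": str(SKOS),
    "dc": str(DC),
    "dcterms": str(DCTERMS),
    "xsd": str(XSD),
    "void": VOID_BASE,
    "owl": str(OWL),
}


class TermKind(enum.Enum):
    Class = "Class"
    Property = "Property"


@dataclass(frozen=True)
class VocabTerm:
    prefix: str
    local_name: str
    uri: str
    term_kind: TermKind

    @property
    def ref(self) -> URIRef:
        return URIRef(self.uri)


class Relation(enum.Enum):
    exactMatch = "exactMatch"
    closeMatch = "closeMatch"


@dataclass(frozen=True)
class AlignmentLink:
    wp_term: VocabTerm
    external_uri: str
    relation: Relation


class VocabLookupError(KeyError):
    pass


class VocabRegistry:
    """(prefix, local_name) -> VocabTerm registry with URI-uniqueness checks."""

    def __init__(self) -> None:
        self._terms: dict[tuple[str, str], VocabTerm] = {}
        self._by_uri: dict[str, VocabTerm] = {}
        self.alignments: list[AlignmentLink] = []

    def register(self, prefix: str, local_name: str, kind: TermKind) -> VocabTerm:
        if prefix not in PREFIXES:
            raise VocabLookupError(f"unknown prefix {prefix!r}")
        uri = PREFIXES[prefix] + local_name
        term = VocabTerm(prefix, local_name, uri, kind)
        key = (prefix, local_name)
        if key in self._terms:
            raise ValueError(f"term {prefix}:{local_name} already registered")
        if uri in self._by_uri:
            raise ValueError(f"URI {uri} already bound to another term")
        self._terms[key] = term
        self._by_uri[uri] = term
        return term

    def resolve(self, prefixed_name: str) -> VocabTerm:
        """Resolve ``"skos:member"``-style names to the registered term."""
        if ":" not in prefixed_name:
            raise VocabLookupError(f"not a prefixed name: {prefixed_name!r}")
        prefix, local = prefixed_name.split(":", 1)
        try:
            return self._terms[(prefix, local)]
        except KeyError:
            raise VocabLookupError(f"unknown term {prefixed_name!r}") from None

    def ref(self, prefixed_name: str) -> URIRef:
        return self.resolve(prefixed_name).ref

    def contains_uri(self, uri: str) -> bool:
        return uri in self._by_uri

    def terms(self, prefix: Optional[str] = None) -> list[VocabTerm]:
        out = list(self._terms.values())
        if prefix is not None:
            out = [t for t in out if t.prefix == prefix]
        return out

    def align(self, prefixed_name: str, external_uri: str, relation: Relation) -> AlignmentLink:
        link = AlignmentLink(self.resolve(prefixed_name), external_uri, relation)
        self.alignments.append(link)
        return link

    def load_alignments_tsv(self, text: str) -> int:
        """Load user alignment rows (columns: wp_term, external_uri, relation)."""
        count = 0
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"alignment TSV line {lineno}: expected 3 columns")
            name, uri, rel = parts
            try:
                relation = Relation(rel)
            except ValueError:
                raise ValueError(
                    f"alignment TSV line {lineno}: relation must be exactMatch or closeMatch"
                ) from None
            self.align(name, uri, relation)
            count += 1
        return count

    def export_vocabulary(self, which: str) -> Graph:
        """Emit declaration triples (plus alignments) for one vocabulary."""
        if which not in ("gpml", "wp"):
            raise ValueError("which must be 'gpml' or 'wp'")
        g = Graph()
        for prefix, base in PREFIXES.items():
            g.bind(prefix, base)
        for term in self.terms(which):
            kind = RDFS.Class if term.term_kind is TermKind.Class else RDF.Property
            g.add((term.ref, RDF.type, kind))
            g.add((term.ref, RDFS.label, Literal(term.local_name, lang="en")))
            g.add((term.ref, RDFS.isDefinedBy, URIRef(PREFIXES[which].rstrip("#"))))
        for link in self.alignments:
            if link.wp_term.prefix != which:
                continue
            pred = SKOS.exactMatch if link.relation is Relation.exactMatch else SKOS.closeMatch
            g.add((link.wp_term.ref, pred, URIRef(link.external_uri)))
        return g


def _populate(reg: VocabRegistry) -> VocabRegistry:
    C, P = TermKind.Class, TermKind.Property

    # GPML graphical layer
    for name in ("Pathway", "DataNode", "Interaction", "Label"):
        reg.register("gpml", name, C)
    for name in (
        "graphId", "ZOrder", "centerX", "centerY", "width", "height",
        "nodeType", "isPartOf", "organism", "organismName",
        "xref", "xrefId", "xrefDataSource",
        "arrowHead", "sourceRef", "targetRef", "source", "target",
        "waypoint", "anchor",
    ):
        reg.register("gpml", name, P)

    # WP biological layer
    for name in (
        "Pathway", "DataNode", "GeneProduct", "Protein", "Rna", "Metabolite",
        "Complex", "Interaction", "DirectedInteraction", "Conversion",
        "Catalysis", "Inhibition",
    ):
        reg.register("wp", name, C)
    for name in (
        "organism", "organismName", "source", "target", "participants",
        "bdbEntrezGene", "bdbEnsembl", "bdbUniprot", "bdbHmdb", "bdbChemspider",
    ):
        reg.register("wp", name, P)

    # reused external terms
    reg.register("rdf", "type", P)
    reg.register("rdfs", "label", P)
    reg.register("rdfs", "isDefinedBy", P)
    reg.register("rdfs", "Class", C)
    reg.register("rdf", "Property", C)
    reg.register("skos", "member", P)
    reg.register("skos", "exactMatch", P)
    reg.register("skos", "closeMatch", P)
    reg.register("dc", "title", P)
    reg.register("dc", "identifier", P)
    reg.register("dc", "source", P)
    reg.register("dcterms", "isPartOf", P)
    reg.register("dcterms", "identifier", P)
    reg.register("dcterms", "title", P)
    reg.register("dcterms", "license", P)
    reg.register("dcterms", "created", P)
    reg.register("void", "Dataset", C)
    reg.register("void", "triples", P)
    reg.register("void", "subset", P)

    # minimal shipped alignment set; extensible via load_alignments_tsv
    reg.align("wp:Pathway", BIOPAX_BASE + "Pathway", Relation.closeMatch)
    reg.align("wp:DirectedInteraction", BIOPAX_BASE + "Conversion", Relation.closeMatch)
    return reg


#: Default registry with both vocabularies and all reused terms.
DEFAULT_REGISTRY = _populate(VocabRegistry())


def resolve(prefixed_name: str) -> VocabTerm:
    return DEFAULT_REGISTRY.resolve(prefixed_name)


def term(prefixed_name: str) -> URIRef:
    return DEFAULT_REGISTRY.ref(prefixed_name)
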