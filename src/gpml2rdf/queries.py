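"""Stock SPARQL queries and their execution.

Ships the endpoint's example queries as ``.rq`` files: three local queries
(species/pathway counts, gene products of one pathway, PubChem compounds
across pathways), two federated queries that join pathway triples with
remote disease and expression endpoints, and the CONSTRUCT query that turns
a drawn interaction into its biological interpretation.

Federated queries (those with a SERVICE clause) are first-class
documentation artifacts but are never executed here: remote endpoints are
outside this package's reliability envelope, and :func:`run_query` refuses
them with a pointer to the query text.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources

from rdflib import Graph

__all__ = ["StoredQuery", "QueryError", "FederatedQueryRefused", "list_queries",
           "get_query", "run_query", "results_to_tsv"]


class QueryError(ValueError):
    pass


class FederatedQueryRefused(RuntimeError):
    pass


@dataclass(frozen=True)
class StoredQuery:
    name: str
    sparql_text: str
    result_schema: tuple[str, ...]
    federated: bool = False
    #: "sparql11" (executable), "legacy" (verbatim pre-1.1 dialect, shipped
    #: for fidelity, not executable), or "construct".
    dialect: str = "sparql11"

    @property
    def description(self) -> str:
        lines = []
        for line in self.sparql_text.splitlines():
            if line.startswith("#"):
                lines.append(line.lstrip("# "))
            elif line.strip():
                break
        return " ".join(lines)


_CATALOG: list[tuple[str, str, tuple[str, ...], bool, str]] = [
    ("species_pathway_counts", "species_pathway_counts.rq",
     ("organism", "label", "numberOfPathways"), False, "sparql11"),
    ("species_pathway_counts_legacy", "species_pathway_counts_legacy.rq",
     ("organism", "label", "numberOfPathways"), False, "legacy"),
    ("gene_products_wp615", "gene_products_wp615.rq",
     ("pathway", "label"), False, "sparql11"),
    ("pubchem_compounds", "pubchem_compounds.rq",
     ("identifier", "pathway"), False, "sparql11"),
    ("federated_disgenet_asthma", "federated_disgenet_asthma.rq",
     ("wpId", "pwtitle", "wpgenes"), True, "sparql11"),
    ("federated_atlas_asthma", "federated_atlas_asthma.rq",
     ("wpURL", "pwTitle", "Ensembl", "EntrezGene", "expressionValue", "pvalue"),
     True, "sparql11"),
    ("gpml_to_wp_interaction_construct", "gpml_to_wp_interaction_construct.rq",
     (), False, "construct"),
]

_SERVICE_RE = re.compile(r"\bSERVICE\b", re.IGNORECASE)


def _load(name: str, filename: str, schema: tuple[str, ...], federated: bool,
          dialect: str) -> StoredQuery:
    text = resources.files("gpml2rdf.data").joinpath(f"queries/{filename}").read_text()
    q = StoredQuery(name, text, schema, federated, dialect)
    if not federated and _SERVICE_RE.search(text):
        raise QueryError(f"query {name}: non-federated query must not use SERVICE")
    return q


def list_queries() -> list[StoredQuery]:
    """All shipped queries, federated ones flagged."""
    return [_load(*entry) for entry in _CATALOG]


def get_query(name: str) -> StoredQuery:
    for entry in _CATALOG:
        if entry[0] == name:
            return _load(*entry)
    raise QueryError(f"no stored query named {name!r}")


def run_query(graph: Graph, query: StoredQuery) -> list[dict]:
    """Execute a stored SELECT query; returns one dict per solution row.

    Missing bindings appear as None.  Federated queries are refused; the
    legacy-dialect query is shipped as documentation and refused with a
    pointer to its normalized variant.
    """
    if query.federated:
        raise FederatedQueryRefused(
            f"query {query.name!r} federates over remote SPARQL endpoints; "
            "it is shipped as documentation only (see its .rq file)"
        )
    if query.dialect == "legacy":
        raise QueryError(
            f"query {query.name!r} uses a pre-SPARQL-1.1 aggregate dialect; "
            "run its normalized variant instead"
        )
    if query.dialect != "sparql11":
        raise QueryError(f"query {query.name!r} is not a SELECT query")
    try:
        result = graph.query(query.sparql_text)
    except Exception as exc:
        raise QueryError(f"query {query.name!r} failed: {exc}") from exc
    rows = []
    for binding in result:
        row = {}
        for var in query.result_schema:
            value = getattr(binding, var, None)
            row[var] = value.toPython() if value is not None else None
        rows.append(row)
    return rows


def results_to_tsv(query: StoredQuery, rows: list[dict]) -> str:
    """Render result rows as TSV with the query's schema as header."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(query.result_schema)
    for row in rows:
        writer.writerow(["" if row[v] is None else row[v] for v in query.result_schema])
    return buf.getvalue()
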