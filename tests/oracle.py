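"""Independent test oracles.

``bgp_join`` is a brute-force SPARQL basic-graph-pattern evaluator written
directly against triple iteration — it never touches rdflib's query engine,
so it can serve as the reference for engine results.  ``count_elements``
walks GPML XML with the standard-library parser, independent of the lxml
path used by the package.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Iterable, Optional


def _is_var(term) -> bool:
    return isinstance(term, str) and term.startswith("?")


def _match(pattern, triple, binding: dict) -> Optional[dict]:
    out = dict(binding)
    for p_term, t_term in zip(pattern, triple):
        if _is_var(p_term):
            if p_term in out:
                if out[p_term] != t_term:
                    return None
            else:
                out[p_term] = t_term
        elif p_term != t_term:
            return None
    return out


def bgp_join(triples: Iterable[tuple], patterns: list[tuple]) -> list[dict]:
    """All solution bindings for a conjunction of triple patterns.

    Variables are ``"?name"`` strings; everything else must compare equal to
    the rdflib term in the triple.  Nested-loop join, exponential in the
    worst case — fine for the fixture sizes used in tests.
    """
    store = list(triples)
    bindings = [{}]
    for pattern in patterns:
        step = []
        for binding in bindings:
            for triple in store:
                extended = _match(pattern, triple, binding)
                if extended is not None:
                    step.append(extended)
        bindings = step
    return bindings


def project_distinct(bindings: list[dict], variables: list[str]) -> set[tuple]:
    return {tuple(b.get(v) for v in variables) for b in bindings}


def count_elements(xml_bytes: bytes) -> dict:
    """Count GPML child elements by local name using xml.etree."""
    root = ET.fromstring(xml_bytes)
    counts: dict[str, int] = {}
    for child in root:
        name = child.tag.rsplit("}", 1)[-1]
        counts[name] = counts.get(name, 0) + 1
    return counts
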