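"""IRIs and prefix tables used throughout the knowledge graph.

Instance data lives under the ``data:`` namespace; the handful of
application-level predicates (collection membership, subject identifier,
age literal, clinical links) live under ``app:``.  Domain classes and
relations reuse OBO-style IRIs: ``part of`` (BFO:0000050), ``located in``
(RO:0001025), ``is about`` (IAO:0000136), ``has quality`` (RO:0000086),
and the IAO textual-definition annotation (IAO:0000115).
"""

from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS, XSD  # re-exported for callers

OBO = Namespace("http://purl.obolibrary.org/obo/")
OBOINOWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")
APP = Namespace("https://w3id.org/semcohort/app#")
DATA = Namespace("https://w3id.org/semcohort/data/")

# relations / annotations
PART_OF = OBO.BFO_0000050
LOCATED_IN = OBO.RO_0001025
IS_ABOUT = OBO.IAO_0000136
HAS_QUALITY = OBO.RO_0000086
DEFINITION = OBO.IAO_0000115

# application vocabulary
SUBJECT = APP.Subject
COLLECTION = APP.Collection
MEMBER_OF_COLLECTION = APP.member_of_collection
SUBJECT_IDENTIFIER = APP.subject_identifier
HAS_DIAGNOSIS = APP.has_diagnosis
HAS_FINDING = APP.has_finding
HAS_STAGE = APP.has_stage
AGE_YEARS = APP.age_years

#: Prefix table emitted at the head of every generated SPARQL query and
#: accepted in CURIEs inside config documents.  Extendable by callers.
PREFIXES: dict[str, str] = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "xsd": str(XSD),
    "obo": str(OBO),
    "oboInOwl": str(OBOINOWL),
    "app": str(APP),
    "data": str(DATA),
}


def expand_curie(token: str, prefixes: dict[str, str] | None = None) -> str:
    """Expand ``prefix:local`` to an absolute IRI; absolute IRIs pass through."""
    if token.startswith(("http://", "https://", "urn:")):
        return token
    table = prefixes or PREFIXES
    prefix, sep, local = token.partition(":")
    if sep and prefix in table:
        return table[prefix] + local
    return token


def to_curie(iri: str, prefixes: dict[str, str] | None = None) -> str:
    """Contract an IRI to the longest-matching prefix, else return it unchanged."""
    table = prefixes or PREFIXES
    best = None
    for prefix, base in table.items():
        if iri.startswith(base) and (best is None or len(base) > len(table[best])):
            best = prefix
    if best is None:
        return iri
    return f"{best}:{iri[len(table[best]):]}"
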