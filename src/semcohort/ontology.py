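"""Load ontology modules and index terms, subclass and partonomy closures.

An :class:`OntologyIndex` is built from one or more RDF documents (Turtle
or N-Triples).  It records, per class, the label, textual definition and
synonyms used by criterion text search, plus the direct ``subClassOf`` and
``part of`` edges.  Transitive closures over both relations are
materialized eagerly; they drive query expansion ("stage I" automatically
covering "stage IA") and the partonomic inference that lets a query for
tumors in the neck return subjects whose tumor sits in the epiglottic
vallecula.

``part of`` edges are accepted in two dialects: a plain object-property
triple ``A obo:BFO_0000050 B`` and the OWL existential-restriction pattern
(``A rdfs:subClassOf [ owl:onProperty part_of ; owl:someValuesFrom B ]``)
that OBO ontologies ship.  Both normalize to a direct edge.

Closures exclude the term itself; :func:`descendants` and :func:`parts_of`
re-add it at the query layer.  Cycles in either relation are hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.exceptions import ParserError
from rdflib.namespace import OWL, RDF, RDFS

from .errors import CycleError, NotFoundError, OntologyParseError
from .namespaces import DEFINITION, OBOINOWL, PART_OF

TermId = str  # absolute IRI


@dataclass
class OntologyTerm:
    id: TermId
    label: str
    definition: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[TermId] = field(default_factory=list)   # direct subClassOf
    part_of: list[TermId] = field(default_factory=list)   # direct part-of wholes


@dataclass
class OntologyIndex:
    """Term table plus materialized transitive closures.

    ``subclass_closure[t]`` is the set of strict ancestors of ``t``;
    ``partof_closure[t]`` the set of strict wholes containing ``t``.
    """

    terms: dict[TermId, OntologyTerm] = field(default_factory=dict)
    subclass_closure: dict[TermId, set[TermId]] = field(default_factory=dict)
    partof_closure: dict[TermId, set[TermId]] = field(default_factory=dict)

    def __contains__(self, term: TermId) -> bool:
        return term in self.terms

    def label(self, term: TermId) -> str:
        t = self.terms.get(term)
        return t.label if t is not None else _local_name(term)

    def descendants(self, term: TermId) -> set[TermId]:
        return descendants(self, term)

    def parts_of(self, whole: TermId) -> set[TermId]:
        return parts_of(self, whole)

    def search(self, query: str):
        return search_terms(self, query)


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            tail = iri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri


_SYNONYM_PREDICATES = (
    OBOINOWL.hasExactSynonym,
    OBOINOWL.hasRelatedSynonym,
    OBOINOWL.hasSynonym,
)

_FORMAT_BY_SUFFIX = {
    ".ttl": "turtle",
    ".nt": "nt",
    ".owl": "xml",
    ".rdf": "xml",
    ".xml": "xml",
}


def _parse_document(document: str | Path, fmt: str | None) -> Graph:
    g = Graph()
    try:
        if isinstance(document, Path) or (
            isinstance(document, str) and "\n" not in document and Path(document).is_file()
        ):
            path = Path(document)
            g.parse(location=str(path), format=fmt or _FORMAT_BY_SUFFIX.get(path.suffix, "turtle"))
        else:
            # N-Triples is a syntactic subset of Turtle, so one parser covers both.
            g.parse(data=str(document), format=fmt or "turtle")
    except (ParserError, SyntaxError) as exc:  # rdflib's BadSyntax subclasses SyntaxError
        raise OntologyParseError(f"cannot parse ontology document: {exc}") from exc
    return g


def load_ontology(*documents: str | Path, format: str | None = None) -> OntologyIndex:
    """Parse RDF documents and build the term index with closures.

    Parameters
    ----------
    documents:
        Paths to ``.ttl``/``.nt`` files, or the document text itself.
    format:
        Optional rdflib format override applied to every document.
    """
    graph = Graph()
    for doc in documents:
        graph += _parse_document(doc, format)

    terms: dict[TermId, OntologyTerm] = {}

    def ensure(iri: URIRef) -> OntologyTerm:
        tid = str(iri)
        if tid not in terms:
            terms[tid] = OntologyTerm(id=tid, label=_local_name(tid))
        return terms[tid]

    # Seed the term table from declared classes and anything with a label.
    for s in graph.subjects(RDF.type, OWL.Class):
        if isinstance(s, URIRef):
            ensure(s)
    for s, o in graph.subject_objects(RDFS.label):
        if isinstance(s, URIRef):
            ensure(s).label = str(o)

    # subclass edges; restriction-style part_of edges ride on subClassOf bnodes
    for s, o in graph.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef):
            continue
        term = ensure(s)
        if isinstance(o, URIRef):
            if str(o) == term.id:
                raise CycleError("subClassOf", [term.id, term.id])
            term.parents.append(str(o))
            ensure(o)
        elif isinstance(o, BNode):
            if (o, RDF.type, OWL.Restriction) in graph and (o, OWL.onProperty, PART_OF) in graph:
                for whole in graph.objects(o, OWL.someValuesFrom):
                    if isinstance(whole, URIRef):
                        if str(whole) == term.id:
                            raise CycleError("part_of", [term.id, term.id])
                        term.part_of.append(str(whole))
                        ensure(whole)

    # plain object-property part_of triples
    for s, o in graph.subject_objects(PART_OF):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            if str(s) == str(o):
                raise CycleError("part_of", [str(s), str(s)])
            term = ensure(s)
            term.part_of.append(str(o))
            ensure(o)

    # annotations
    for tid, term in terms.items():
        iri = URIRef(tid)
        definition = graph.value(iri, DEFINITION) or graph.value(iri, RDFS.comment)
        if isinstance(definition, Literal):
            term.definition = str(definition)
        syns = set()
        for pred in _SYNONYM_PREDICATES:
            for o in graph.objects(iri, pred):
                syns.add(str(o))
        term.synonyms = sorted(syns)
        term.parents = sorted(set(term.parents))
        term.part_of = sorted(set(term.part_of))

    index = OntologyIndex(terms=terms)
    index.subclass_closure = _transitive_closure(
        "subClassOf", {t: term.parents for t, term in terms.items()}
    )
    index.partof_closure = _transitive_closure(
        "part_of", {t: term.part_of for t, term in terms.items()}
    )
    return index


def _transitive_closure(
    relation: str, edges: Mapping[TermId, Iterable[TermId]]
) -> dict[TermId, set[TermId]]:
    """Reflexive-free transitive closure by memoized DFS; cycles are errors."""
    closure: dict[TermId, set[TermId]] = {}
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {t: WHITE for t in edges}
    stack_path: list[TermId] = []

    def visit(node: TermId) -> set[TermId]:
        if color.get(node, BLACK) == BLACK and node in closure:
            return closure[node]
        if color.get(node) == GRAY:
            i = stack_path.index(node)
            raise CycleError(relation, stack_path[i:] + [node])
        color[node] = GRAY
        stack_path.append(node)
        reach: set[TermId] = set()
        for parent in edges.get(node, ()):
            reach.add(parent)
            reach |= visit(parent)
        stack_path.pop()
        color[node] = BLACK
        closure[node] = reach
        if node in reach:
            raise CycleError(relation, [node, node])
        return reach

    for t in edges:
        visit(t)
    return closure


def _require(index: OntologyIndex, term: TermId) -> None:
    if term not in index.terms:
        raise NotFoundError(f"unknown term: {term}")


def descendants(index: OntologyIndex, term: TermId) -> set[TermId]:
    """The term itself plus every term whose ancestor set contains it."""
    _require(index, term)
    out = {term}
    for t, ancestors in index.subclass_closure.items():
        if term in ancestors:
            out.add(t)
    return out


def parts_of(index: OntologyIndex, whole: TermId) -> set[TermId]:
    """The whole itself plus every term contained in it (transitively)."""
    _require(index, whole)
    out = {whole}
    for t, wholes in index.partof_closure.items():
        if whole in wholes:
            out.add(t)
    return out


def search_terms(index: OntologyIndex, query: str) -> list[tuple[TermId, str, str]]:
    """Case-insensitive substring search over labels, synonyms and definitions.

    Returns ``(term id, label, matched_field)`` tuples ordered by match
    field (label < synonym < definition), then label, then IRI — a total,
    reproducible order.  An empty query returns an empty list.
    """
    q = query.strip().lower()
    if not q:
        return []
    rank = {"label": 0, "synonym": 1, "definition": 2}
    hits: list[tuple[int, str, str, str]] = []
    for tid, term in index.terms.items():
        if q in term.label.lower():
            field_name = "label"
        elif any(q in s.lower() for s in term.synonyms):
            field_name = "synonym"
        elif q in term.definition.lower():
            field_name = "definition"
        else:
            continue
        hits.append((rank[field_name], term.label, tid, field_name))
    hits.sort()
    return [(tid, label, field_name) for _, label, tid, field_name in hits]
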