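"""Merged knowledge graph with materialized inference and query building.

The store holds the instance triples produced by the transformation
(``asserted``) plus an ``inferred`` set materialized at load time:

1. *Type propagation over the class taxonomy* — an instance typed C is
   inferred typed every ancestor of C, so a query for "lung cancer"
   subjects reaches lung-adenocarcinoma instances.
2. *Partonomic propagation over tumor locations* — a tumor located in an
   anatomical instance typed C is inferred located in C and in every
   transitive whole of C (punning the anatomy class IRIs as region
   referents), so a query for tumors in the neck returns subjects whose
   tumor sits in the epiglottic vallecula.

Inference runs forward to a fixpoint; re-running it adds nothing.

Queries are built in three parts, mirroring how a dynamic query builder
assembles SPARQL for a triple store: a header of prefixes plus the SELECT
line, one basic-graph-pattern block per attribute clause (each attribute
introduces fresh bind variables), and finally the value filters.  The
emitted text is valid SPARQL; :func:`match` evaluates the same
:class:`QuerySpec` with this package's own conjunctive matcher, and the
two routes must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Number

from rdflib import Literal, URIRef, Variable
from rdflib.namespace import RDF

from .errors import ConsistencyError, NotFoundError, UsageError, ValidationError
from .namespaces import (
    AGE_YEARS,
    APP,
    COLLECTION,
    HAS_DIAGNOSIS,
    HAS_FINDING,
    HAS_QUALITY,
    HAS_STAGE,
    IS_ABOUT,
    LOCATED_IN,
    MEMBER_OF_COLLECTION,
    PREFIXES,
    SUBJECT,
    SUBJECT_IDENTIFIER,
    to_curie,
)
from .ontology import OntologyIndex, TermId
from .transform import TripleSet, merge_graphs

#: queryable features and whether they are class-valued or numeric
CLASS_FEATURES = ("disease_type", "tumor_site", "sex", "stage")
NUMERIC_FEATURES = ("age",)
FEATURES = CLASS_FEATURES + NUMERIC_FEATURES

_SUBJ = Variable("subject")
_SUBJ_ID = Variable("subject_id")


def _feature_patterns(feature: str, alias: str):
    """Triple patterns linking ?subject to the feature's value variable.

    For ``tumor_site`` the value variable binds the ``located in`` referent
    itself: the asserted anatomical instance, or — through the materialized
    partonomy inference — a region class IRI, so filtering on the neck
    class reaches tumors asserted in any part of the neck.
    """
    v = Variable(alias)
    if feature == "disease_type":
        dx, inst = Variable(f"{alias}_dx"), Variable(f"{alias}_i")
        return [(_SUBJ, HAS_DIAGNOSIS, dx), (dx, IS_ABOUT, inst), (inst, RDF.type, v)]
    if feature == "tumor_site":
        tumor = Variable(f"{alias}_t")
        return [(_SUBJ, HAS_FINDING, tumor), (tumor, LOCATED_IN, v)]
    if feature == "sex":
        q = Variable(f"{alias}_q")
        return [(_SUBJ, HAS_QUALITY, q), (q, RDF.type, v)]
    if feature == "stage":
        st = Variable(f"{alias}_s")
        return [(_SUBJ, HAS_STAGE, st), (st, RDF.type, v)]
    if feature == "age":
        return [(_SUBJ, AGE_YEARS, v)]
    raise UsageError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def _retrieval_patterns(feature: str, alias: str):
    """Feature paths used for asserted-value retrieval (export, counting).

    Identical to the query paths except that ``tumor_site`` resolves to
    the asserted class of the anatomical instance rather than the
    inference-expanded location referent.
    """
    if feature == "tumor_site":
        v = Variable(alias)
        tumor, site = Variable(f"{alias}_t"), Variable(f"{alias}_i")
        return [(_SUBJ, HAS_FINDING, tumor), (tumor, LOCATED_IN, site), (site, RDF.type, v)]
    return _feature_patterns(feature, alias)


@dataclass
class AttributeClause:
    """One attribute added to a query; introduces fresh bind variables.

    The feature's value is bound to ``?<alias>`` (alias defaults to the
    feature name) and can be filtered in the filter section.
    """

    feature: str
    alias: str | None = None

    @property
    def value_var(self) -> str:
        return self.alias or self.feature

    def patterns(self):
        return _feature_patterns(self.feature, self.value_var)


@dataclass
class Filter:
    """A value filter over a bound variable.

    ``op`` is one of ``=``, ``in``, ``>``, ``>=``, ``<``, ``<=``; values
    are term IRIs (class features) or numbers (numeric features).
    """

    var: str
    op: str
    value: object  # TermId | number | list[TermId]


@dataclass
class QuerySpec:
    select_vars: list[str] = field(default_factory=lambda: ["subject_id"])
    attributes: list[AttributeClause] = field(default_factory=list)
    filters: list[Filter] = field(default_factory=list)

    def compile(self):
        """Validate and return (triple patterns, filters)."""
        if not self.select_vars:
            raise ValidationError("select_vars must be non-empty")
        patterns = [
            (_SUBJ, RDF.type, SUBJECT),
            (_SUBJ, SUBJECT_IDENTIFIER, _SUBJ_ID),
        ]
        bound = {"subject", "subject_id"}
        for clause in self.attributes:
            pats = clause.patterns()
            patterns.extend(pats)
            for t in pats:
                for term in t:
                    if isinstance(term, Variable):
                        bound.add(str(term))
        for f in self.filters:
            if f.var not in bound:
                raise ValidationError(f"filter over unbound variable ?{f.var}")
            if f.op not in ("=", "in", ">", ">=", "<", "<="):
                raise ValidationError(f"unknown filter operator {f.op!r}")
        for v in self.select_vars:
            if v not in bound:
                raise ValidationError(f"select variable ?{v} is not bound")
        return patterns, list(self.filters)


@dataclass
class KnowledgeGraph:
    asserted: TripleSet
    inferred: TripleSet
    ontology: OntologyIndex
    # derived indexes, built at load
    node_to_id: dict[URIRef, str] = field(default_factory=dict)
    id_to_node: dict[str, URIRef] = field(default_factory=dict)
    subject_collection: dict[str, str] = field(default_factory=dict)

    def all_subject_ids(self) -> set[str]:
        return set(self.id_to_node)

    def combined(self) -> set:
        return self.asserted.triples | self.inferred.triples


def build_store(
    instance_graphs: list[TripleSet], ontology: OntologyIndex
) -> KnowledgeGraph:
    """Merge instance graphs and materialize inference to a fixpoint.

    Raises :class:`ConsistencyError` if any instance is typed by a class
    IRI outside both the application vocabulary and the loaded ontology.
    """
    asserted = merge_graphs(list(instance_graphs))
    app_ns = str(APP)
    for s, p, o in asserted:
        if p == RDF.type and isinstance(o, URIRef):
            iri = str(o)
            if not iri.startswith(app_ns) and iri not in ontology:
                raise ConsistencyError(f"instance {s} typed by unknown class {iri}")

    inferred: set = set()
    work = set(asserted.triples)
    while True:
        new: set = set()
        combined = work | inferred
        types: dict[object, set[str]] = {}
        for s, p, o in combined:
            if p == RDF.type and isinstance(o, URIRef):
                types.setdefault(s, set()).add(str(o))
        # rule 1: propagate class ancestors onto typed instances
        for inst, classes in types.items():
            for c in classes:
                for ancestor in ontology.subclass_closure.get(c, ()):
                    t = (inst, RDF.type, URIRef(ancestor))
                    if t not in combined:
                        new.add(t)
        # rule 2: propagate part-of wholes onto located-in targets
        for s, p, o in combined:
            if p == LOCATED_IN:
                for c in types.get(o, ()):
                    if c not in ontology:
                        continue
                    for whole in {c} | ontology.partof_closure.get(c, set()):
                        t = (s, LOCATED_IN, URIRef(whole))
                        if t not in combined:
                            new.add(t)
        if not new:
            break
        inferred |= new

    kg = KnowledgeGraph(
        asserted=asserted,
        inferred=TripleSet(inferred - asserted.triples),
        ontology=ontology,
    )
    coll_labels: dict[URIRef, str] = {}
    from rdflib.namespace import RDFS

    for s, p, o in asserted:
        if p == RDFS.label and isinstance(o, Literal):
            coll_labels[s] = str(o)
    memberships: dict[URIRef, URIRef] = {}
    for s, p, o in asserted:
        if p == MEMBER_OF_COLLECTION:
            memberships[s] = o
    for s, p, o in asserted:
        if p == SUBJECT_IDENTIFIER and isinstance(o, Literal):
            sid = str(o)
            kg.node_to_id[s] = sid
            kg.id_to_node[sid] = s
            coll = memberships.get(s)
            if coll is not None:
                kg.subject_collection[sid] = coll_labels.get(coll, str(coll))
    return kg


# ---------------------------------------------------------------------------
# three-part query construction


def _render_term(term) -> str:
    if isinstance(term, Variable):
        return f"?{term}"
    if isinstance(term, URIRef):
        curie = to_curie(str(term))
        return curie if curie != str(term) and "/" not in curie.split(":", 1)[1] else f"<{term}>"
    if isinstance(term, Literal):
        return term.n3()
    raise UsageError(f"cannot render query term {term!r}")


def _render_filter_value(value) -> str:
    if isinstance(value, bool):
        raise UsageError("boolean filter values are not supported")
    if isinstance(value, Number):
        return repr(value)
    return _render_term(URIRef(str(value)))


def build_query(spec: QuerySpec) -> str:
    """Emit the spec as SPARQL text in three sections.

    Section 1: the outer query — prefix table and SELECT line.  Section 2:
    one basic-graph-pattern block per attribute clause, each introducing
    its bind variables.  Section 3: the FILTER clauses.  The text is
    deterministic and executable against any SPARQL engine holding the
    asserted∪inferred triples.
    """
    patterns, filters = spec.compile()
    lines = [f"PREFIX {p}: <{iri}>" for p, iri in sorted(PREFIXES.items())]
    lines.append("SELECT DISTINCT " + " ".join(f"?{v}" for v in spec.select_vars))
    lines.append("WHERE {")
    for s, p, o in patterns:
        lines.append(f"  {_render_term(s)} {_render_term(p)} {_render_term(o)} .")
    for f in filters:
        if f.op == "in":
            values = ", ".join(_render_filter_value(v) for v in f.value)
            lines.append(f"  FILTER(?{f.var} IN ({values}))")
        else:
            lines.append(f"  FILTER(?{f.var} {f.op} {_render_filter_value(f.value)})")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# native conjunctive matcher


def _to_python(term):
    if isinstance(term, Literal):
        return term.toPython()
    return str(term)


def _passes(binding_value, flt: Filter) -> bool:
    val = _to_python(binding_value)
    if flt.op == "=":
        return str(val) == str(flt.value) if not isinstance(val, Number) else val == flt.value
    if flt.op == "in":
        return str(val) in {str(v) for v in flt.value}
    if not isinstance(val, Number):
        return False
    ref = flt.value
    return {
        ">": val > ref,
        ">=": val >= ref,
        "<": val < ref,
        "<=": val <= ref,
    }[flt.op]


def _evaluate(patterns, triples) -> list[dict[str, object]]:
    """Backtracking join of a conjunctive pattern list over a triple set."""
    by_pred: dict[URIRef, list[tuple]] = {}
    for s, p, o in triples:
        by_pred.setdefault(p, []).append((s, o))
    bindings: list[dict[str, object]] = [{}]
    for s_pat, p_pat, o_pat in patterns:
        candidates = by_pred.get(p_pat, [])
        next_bindings = []
        for b in bindings:
            s_bound = b.get(str(s_pat)) if isinstance(s_pat, Variable) else s_pat
            o_bound = b.get(str(o_pat)) if isinstance(o_pat, Variable) else o_pat
            for s, o in candidates:
                if s_bound is not None and s != s_bound:
                    continue
                if o_bound is not None and o != o_bound:
                    continue
                nb = dict(b)
                if isinstance(s_pat, Variable):
                    nb[str(s_pat)] = s
                if isinstance(o_pat, Variable):
                    nb[str(o_pat)] = o
                next_bindings.append(nb)
        bindings = next_bindings
        if not bindings:
            break
    return bindings


def match(graph: KnowledgeGraph, spec: QuerySpec) -> list[tuple]:
    """Evaluate the spec over asserted ∪ inferred triples.

    Returns distinct projected rows (tuples aligned with
    ``spec.select_vars``, rdflib terms converted to plain Python values),
    sorted so the order is reproducible.
    """
    patterns, filters = spec.compile()
    rows = set()
    for b in _evaluate(patterns, graph.combined()):
        if all(_passes(b[f.var], f) for f in filters):
            rows.add(tuple(_to_python(b[v]) for v in spec.select_vars))
    return sorted(rows, key=lambda r: tuple(str(x) for x in r))


# ---------------------------------------------------------------------------
# cohort-facing retrieval


def _feature_values(graph: KnowledgeGraph, feature: str, asserted_only: bool = True):
    """Yield (subject id, asserted value term) pairs for a feature."""
    patterns = [
        (_SUBJ, RDF.type, SUBJECT),
        (_SUBJ, SUBJECT_IDENTIFIER, _SUBJ_ID),
        *_retrieval_patterns(feature, feature),
    ]
    source = graph.asserted.triples if asserted_only else graph.combined()
    for b in _evaluate(patterns, source):
        yield _to_python(b["subject_id"]), b[feature]


def expansion_terms(
    ontology: OntologyIndex, feature: str, term: TermId, expand: bool
) -> set[TermId]:
    """The class IRIs a criterion term covers.

    Without expansion: the term itself.  With expansion: the term plus its
    subclass descendants, and — for anatomical sites — everything that is
    transitively part of it.
    """
    if term not in ontology:
        raise NotFoundError(f"unknown term: {term}")
    if not expand:
        return {term}
    terms = ontology.descendants(term)
    if feature == "tumor_site":
        terms |= ontology.parts_of(term)
    return terms


def subjects_by_class(
    graph: KnowledgeGraph,
    feature: str,
    term: TermId,
    expand: bool = True,
) -> set[str]:
    """Subject ids whose asserted value for the feature falls under ``term``.

    With ``expand`` the term covers its subclass descendants (stage I
    automatically includes stage IA) and, for tumor sites, its transitive
    parts (neck includes throat and epiglottic vallecula).
    """
    if feature not in CLASS_FEATURES:
        raise UsageError(f"{feature!r} is not a class-valued feature")
    allowed = expansion_terms(graph.ontology, feature, term, expand)
    return {
        sid
        for sid, value in _feature_values(graph, feature, asserted_only=True)
        if str(value) in allowed
    }


def subjects_by_number(
    graph: KnowledgeGraph,
    feature: str,
    low: float | None = None,
    high: float | None = None,
    low_strict: bool = False,
    high_strict: bool = False,
) -> set[str]:
    """Subject ids whose numeric feature satisfies the bounds.

    Subjects with no value for the feature are never returned.
    """
    if feature not in NUMERIC_FEATURES:
        raise UsageError(f"{feature!r} is not a numeric feature")
    if low is None and high is None:
        raise UsageError("at least one bound is required")
    if low is not None and high is not None and low > high:
        raise UsageError("low bound exceeds high bound")
    out = set()
    for sid, value in _feature_values(graph, feature, asserted_only=True):
        v = _to_python(value)
        if not isinstance(v, Number):
            continue
        if low is not None and (v <= low if low_strict else v < low):
            continue
        if high is not None and (v >= high if high_strict else v > high):
            continue
        out.add(sid)
    return out
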