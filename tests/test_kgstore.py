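"""Store construction, inference materialization, query building/matching."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

import semcohort.fixtures as fx
from semcohort.errors import ConsistencyError, NotFoundError, UsageError, ValidationError
from semcohort.kgstore import (
    AttributeClause,
    Filter,
    QuerySpec,
    build_query,
    build_store,
    match,
    subjects_by_class,
    subjects_by_number,
)
from semcohort.namespaces import (
    AGE_YEARS,
    HAS_FINDING,
    LOCATED_IN,
    SUBJECT,
    SUBJECT_IDENTIFIER,
)
from semcohort.ontology import load_ontology
from semcohort.transform import TripleSet

from conftest import query_spec_suite


def tiny_store(ages: dict[str, int]):
    """A minimal store with just subjects and age literals."""
    onto = load_ontology(
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        '<https://w3id.org/semcohort/test/T> a owl:Class .\n'
    )
    triples = set()
    for sid, age in ages.items():
        s = URIRef(f"https://w3id.org/semcohort/data/T/{sid}")
        triples.add((s, RDF.type, SUBJECT))
        triples.add((s, SUBJECT_IDENTIFIER, Literal(sid)))
        if age is not None:
            triples.add((s, AGE_YEARS, Literal(age, datatype=XSD.integer)))
    return build_store([TripleSet(triples)], onto)


class TestBuildStore:
    def test_vallecula_tumor_inferred_in_throat_and_neck(self, repo, store):
        """Partonomic inference: a tumor asserted in the epiglottic
        vallecula is inferred located in the throat and the neck."""
        row = next(
            t for t in repo.truth
            if t.collection == "HN-1" and t.observed("site") == fx.VALLECULA
        )
        from semcohort.transform import subject_node

        subj = subject_node("HN-1", row.subject_id)
        (tumor,) = [o for s, p, o in store.asserted if s == subj and p == HAS_FINDING]
        inferred = store.inferred.triples
        assert (tumor, LOCATED_IN, URIRef(fx.THROAT)) in inferred
        assert (tumor, LOCATED_IN, URIRef(fx.NECK)) in inferred

    def test_type_propagation_to_ancestors(self, store):
        """An instance typed lung adenocarcinoma is inferred typed lung
        cancer and cancer."""
        ad_instances = [
            s for s, p, o in store.asserted
            if p == RDF.type and str(o) == fx.LUNG_AD
        ]
        assert ad_instances
        inferred = store.inferred.triples
        for inst in ad_instances:
            assert (inst, RDF.type, URIRef(fx.LUNG_CANCER)) in inferred
            assert (inst, RDF.type, URIRef(fx.CANCER)) in inferred

    def test_empty_instance_graph(self, ontology):
        kg = build_store([TripleSet()], ontology)
        assert len(kg.inferred) == 0

    def test_inferred_disjoint_from_asserted(self, store):
        assert store.inferred.triples.isdisjoint(store.asserted.triples)

    def test_inference_fixpoint(self, store, ontology):
        """Re-running inference on asserted ∪ inferred adds nothing."""
        again = build_store([TripleSet(store.combined())], ontology)
        assert again.combined() == store.combined()
        assert len(again.inferred) == 0

    def test_unknown_class_is_consistency_error(self, ontology):
        s = URIRef("https://w3id.org/semcohort/data/T/S1")
        bad = TripleSet({(s, RDF.type, URIRef("https://nope.example/Ghost"))})
        with pytest.raises(ConsistencyError, match="Ghost"):
            build_store([bad], ontology)

    def test_monotonicity_of_answers(self, repo, ontology):
        """Adding instance triples never removes a query answer."""
        from semcohort.patterns import load_patterns, load_rules
        from semcohort.transform import read_collection_sheet, transform_collection

        patterns = load_patterns(repo.patterns_yaml)
        ruleset = load_rules(repo.rules_yaml, patterns)
        graphs = {}
        for name, sheet in repo.sheets.items():
            records = read_collection_sheet(sheet, ruleset.id_columns[name], collection=name)
            graphs[name], _ = transform_collection(
                records, ruleset.for_collection(name), patterns, ontology
            )
        small = build_store([graphs["HN-1"]], ontology)
        big = build_store(list(graphs.values()), ontology)
        for spec in query_spec_suite():
            assert set(match(small, spec)) <= set(match(big, spec))


class TestBuildQuery:
    def test_three_sections_in_order(self):
        """Header (prefixes + SELECT), graph patterns, then filters."""
        spec = QuerySpec(
            attributes=[AttributeClause("disease_type")],
            filters=[Filter("disease_type", "=", fx.LUNG_AD)],
        )
        text = build_query(spec)
        prefix_pos = text.index("PREFIX ")
        select_pos = text.index("SELECT DISTINCT ?subject_id")
        pattern_pos = text.index("?subject rdf:type app:Subject")
        filter_pos = text.index("FILTER(")
        assert prefix_pos < select_pos < pattern_pos < filter_pos
        assert text.rstrip().endswith("}")

    def test_no_attributes_is_select_all(self):
        text = build_query(QuerySpec())
        assert "FILTER" not in text
        assert "?subject app:subject_identifier ?subject_id" in text

    def test_each_attribute_adds_bind_variables(self):
        one = build_query(QuerySpec(attributes=[AttributeClause("sex")]))
        two = build_query(
            QuerySpec(attributes=[AttributeClause("sex"), AttributeClause("age")])
        )
        assert "?sex_q" in one and "?age" not in one
        assert "?sex_q" in two and "?age" in two

    def test_filter_over_unbound_variable_rejected(self):
        spec = QuerySpec(filters=[Filter("ghost", "=", fx.MALE)])
        with pytest.raises(ValidationError, match="ghost"):
            build_query(spec)

    def test_empty_select_rejected(self):
        with pytest.raises(ValidationError):
            build_query(QuerySpec(select_vars=[]))

    def test_deterministic_text(self):
        spec = QuerySpec(
            attributes=[AttributeClause("stage")],
            filters=[Filter("stage", "in", [fx.STAGE_I, fx.STAGE_II])],
        )
        assert build_query(spec) == build_query(spec)


class TestMatch:
    def test_disease_count_matches_truth(self, repo, store):
        expected = {
            t.subject_id for t in repo.truth if t.observed("diagnosis") == fx.LUNG_AD
        }
        spec = QuerySpec(
            attributes=[AttributeClause("disease_type")],
            filters=[Filter("disease_type", "=", fx.LUNG_AD)],
        )
        assert {r[0] for r in match(store, spec)} == expected

    def test_neck_query_returns_vallecula_subjects(self, repo, store):
        spec = QuerySpec(
            attributes=[AttributeClause("tumor_site")],
            filters=[Filter("tumor_site", "=", fx.NECK)],
        )
        found = {r[0] for r in match(store, spec)}
        vallecula = {
            t.subject_id for t in repo.truth if t.observed("site") == fx.VALLECULA
        }
        assert vallecula and vallecula <= found

    def test_empty_store(self, ontology):
        kg = build_store([TripleSet()], ontology)
        assert match(kg, QuerySpec()) == []

    def test_dual_path_equivalence(self, store, rdflib_store_graph):
        """Executing the generated SPARQL text returns exactly the same
        binding sets as the native matcher, for every suite spec."""
        for spec in query_spec_suite():
            mine = match(store, spec)
            sparql = sorted(
                {
                    tuple(v.toPython() for v in row)
                    for row in rdflib_store_graph.query(build_query(spec))
                }
            )
            assert sparql == mine, build_query(spec)


class TestSubjectsByClass:
    def test_stage_expansion_includes_substages(self, repo, store):
        got = subjects_by_class(store, "stage", fx.STAGE_I, expand=True)
        expected = {
            t.subject_id
            for t in repo.truth
            if t.observed("stage") in {fx.STAGE_I, fx.STAGE_IA, fx.STAGE_IB}
        }
        assert got == expected

    def test_exact_vs_expanded_strict_subset(self, store):
        exact = subjects_by_class(store, "stage", fx.STAGE_I, expand=False)
        expanded = subjects_by_class(store, "stage", fx.STAGE_I, expand=True)
        assert exact < expanded

    def test_expansion_equals_union_of_exact_sets(self, store, ontology):
        """Expanded retrieval is the union of exact sets over the expansion."""
        from semcohort.kgstore import expansion_terms

        for feature, term in (
            ("stage", fx.STAGE_I),
            ("tumor_site", fx.NECK),
            ("disease_type", fx.LUNG_CANCER),
        ):
            union = set()
            for t in expansion_terms(ontology, feature, term, True):
                union |= subjects_by_class(store, feature, t, expand=False)
            assert subjects_by_class(store, feature, term, expand=True) == union

    def test_term_without_instances(self, store):
        assert subjects_by_class(store, "tumor_site", fx.MOUTH, expand=False) == set()

    def test_unknown_term(self, store):
        with pytest.raises(NotFoundError):
            subjects_by_class(store, "disease_type", "https://nope.example/X")


class TestSubjectsByNumber:
    def test_above_sixty_strict(self):
        kg = tiny_store({"a": 59, "b": 60, "c": 61, "d": 75})
        assert subjects_by_number(kg, "age", low=60, low_strict=True) == {"c", "d"}

    def test_nonstrict_zero_lower_bound_returns_all_with_age(self):
        kg = tiny_store({"a": 59, "b": 60, "c": None})
        assert subjects_by_number(kg, "age", low=0) == {"a", "b"}

    def test_missing_age_never_matches(self):
        kg = tiny_store({"a": 70, "b": None})
        assert subjects_by_number(kg, "age", low=0, high=200) == {"a"}

    def test_no_bounds_rejected(self):
        kg = tiny_store({"a": 70})
        with pytest.raises(UsageError):
            subjects_by_number(kg, "age")
        with pytest.raises(UsageError):
            subjects_by_number(kg, "age", low=80, high=60)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        low=st.one_of(st.none(), st.integers(30, 90)),
        high=st.one_of(st.none(), st.integers(30, 90)),
        low_strict=st.booleans(),
        high_strict=st.booleans(),
    )
    def test_matches_linear_scan_oracle(self, low, high, low_strict, high_strict):
        rng = random.Random(11)
        ages = {f"s{i}": rng.randint(30, 90) for i in range(30)}
        kg = tiny_store(ages)
        if low is None and high is None:
            return
        if low is not None and high is not None and low > high:
            low, high = high, low
        expected = set()
        for sid, age in ages.items():
            if low is not None and (age <= low if low_strict else age < low):
                continue
            if high is not None and (age >= high if high_strict else age > high):
                continue
            expected.add(sid)
        got = subjects_by_number(
            kg, "age", low=low, high=high, low_strict=low_strict, high_strict=high_strict
        )
        assert got == expected
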