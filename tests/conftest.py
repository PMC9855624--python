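"""Shared fixtures: the synthetic repository, its harmonized store, and
a suite of query specs exercised by both the matcher and the SPARQL path."""

from __future__ import annotations

import pytest

import semcohort.fixtures as fx
from semcohort.api import create_app
from semcohort.catalog import load_catalog
from semcohort.fixtures import FixtureSpec, generate_repository
from semcohort.kgstore import AttributeClause, Filter, QuerySpec
from semcohort.pipeline import harmonize_repository


@pytest.fixture(scope="session")
def repo():
    return generate_repository(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def pipeline(repo):
    """(knowledge graph, per-collection reports, ontology index)."""
    return harmonize_repository(repo)


@pytest.fixture(scope="session")
def store(pipeline):
    return pipeline[0]


@pytest.fixture(scope="session")
def ontology(pipeline):
    return pipeline[2]


@pytest.fixture(scope="session")
def catalog(repo):
    return load_catalog(repo.catalog_yaml)


@pytest.fixture(scope="session")
def app(store, catalog):
    return create_app(store, catalog)


def query_spec_suite() -> list[QuerySpec]:
    """Query specs covering every feature, operator, and section shape."""
    return [
        QuerySpec(),  # select-all-subjects
        QuerySpec(
            attributes=[AttributeClause("disease_type")],
            filters=[Filter("disease_type", "=", fx.LUNG_AD)],
        ),
        QuerySpec(
            attributes=[AttributeClause("disease_type")],
            filters=[Filter("disease_type", "in", [fx.LUNG_AD, fx.LUNG_LCC])],
        ),
        QuerySpec(
            attributes=[AttributeClause("tumor_site")],
            filters=[Filter("tumor_site", "=", fx.NECK)],
        ),
        QuerySpec(
            attributes=[AttributeClause("tumor_site")],
            filters=[Filter("tumor_site", "=", fx.LUNG)],
        ),
        QuerySpec(
            attributes=[AttributeClause("sex")],
            filters=[Filter("sex", "=", fx.MALE)],
        ),
        QuerySpec(
            attributes=[AttributeClause("stage")],
            filters=[Filter("stage", "=", fx.STAGE_I)],
        ),
        QuerySpec(
            select_vars=["subject_id", "age"],
            attributes=[AttributeClause("age")],
            filters=[Filter("age", ">", 60)],
        ),
        QuerySpec(
            attributes=[AttributeClause("age")],
            filters=[Filter("age", ">=", 60), Filter("age", "<=", 70)],
        ),
        QuerySpec(
            attributes=[
                AttributeClause("sex"),
                AttributeClause("disease_type"),
                AttributeClause("age"),
            ],
            filters=[
                Filter("sex", "=", fx.MALE),
                Filter("disease_type", "=", fx.LUNG_AD),
                Filter("age", ">", 60),
            ],
        ),
    ]


@pytest.fixture(scope="session")
def rdflib_store_graph(store):
    """The asserted∪inferred triples loaded into rdflib for SPARQL checks."""
    from rdflib import Graph

    g = Graph()
    for t in store.combined():
        g.add(t)
    return g
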