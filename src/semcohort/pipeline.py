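"""End-to-end convenience: sheets + configs + ontology → knowledge graph."""

from __future__ import annotations

from .fixtures import FixtureRepository
from .kgstore import KnowledgeGraph, build_store
from .ontology import OntologyIndex, load_ontology
from .patterns import load_patterns, load_rules
from .transform import TransformReport, read_collection_sheet, transform_collection


def harmonize_repository(
    repo: FixtureRepository,
) -> tuple[KnowledgeGraph, dict[str, TransformReport], OntologyIndex]:
    """Run the full harmonization pipeline over a generated repository.

    Loads the ontology modules, patterns and rules, transforms every
    collection sheet, merges the per-collection graphs and materializes
    inference.  Returns the store, the per-collection transformation
    reports, and the ontology index.
    """
    ontology = load_ontology(*repo.ontology_docs.values())
    patterns = load_patterns(repo.patterns_yaml)
    ruleset = load_rules(repo.rules_yaml, patterns)
    graphs = []
    reports: dict[str, TransformReport] = {}
    for name, sheet in repo.sheets.items():
        records = read_collection_sheet(
            sheet, id_column=ruleset.id_columns[name], collection=name
        )
        triples, report = transform_collection(
            records, ruleset.for_collection(name), patterns, ontology
        )
        graphs.append(triples)
        reports[name] = report
    store = build_store(graphs, ontology)
    return store, reports, ontology
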