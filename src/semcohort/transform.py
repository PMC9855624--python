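"""Apply mapping rules and patterns to collection sheets, emitting RDF.

The transformation walks every row of a delimited clinical sheet, resolves
each rule-covered cell through the collection's value dialect, and
instantiates the bound representation pattern.  Unmapped tokens and
missing cells never abort the run; they are tallied in a
:class:`TransformReport` so partial harmonization remains possible while
the dialect maps are still being surveyed.

Serialization to N-Triples is canonical (statement lines sorted), so the
same inputs always produce byte-identical output.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .errors import DuplicateError, UsageError, ValidationError
from .namespaces import (
    COLLECTION,
    DATA,
    MEMBER_OF_COLLECTION,
    SUBJECT,
    SUBJECT_IDENTIFIER,
)
from .ontology import OntologyIndex
from .patterns import (
    MISSING,
    MappingRule,
    RepresentationPattern,
    Unmapped,
    mint_instance_iri,
    resolve_value,
)

Triple = tuple[URIRef, URIRef, object]


@dataclass
class SubjectRecord:
    collection: str
    subject_id: str
    raw_values: dict[str, str] = field(default_factory=dict)


@dataclass
class TripleSet:
    """A set of absolute-IRI triples (rdflib terms)."""

    triples: set[Triple] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def add(self, triple: Triple) -> None:
        self.triples.add(triple)


@dataclass
class TransformReport:
    collection: str
    n_rows: int = 0
    n_triples: int = 0
    mapped_cells: int = 0
    missing: dict[str, int] = field(default_factory=dict)
    unmapped: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "collection": self.collection,
            "rows": self.n_rows,
            "triples": self.n_triples,
            "mapped_cells": self.mapped_cells,
            "missing_cells": dict(sorted(self.missing.items())),
            "unmapped_tokens": {
                col: dict(sorted(tokens.items()))
                for col, tokens in sorted(self.unmapped.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def subject_node(collection: str, subject_id: str) -> URIRef:
    return mint_instance_iri(collection, subject_id)


def collection_node(collection: str) -> URIRef:
    return mint_instance_iri("collection", collection)


def read_collection_sheet(
    document: str | Path,
    id_column: str,
    collection: str | None = None,
    delimiter: str | None = None,
) -> list[SubjectRecord]:
    """Read a CSV/TSV clinical sheet into one record per row.

    The delimiter is sniffed from the file extension (``.tsv`` means tab)
    unless given explicitly; raw cell values are kept verbatim as strings.
    Duplicate subject identifiers are rejected.
    """
    if isinstance(document, (str, Path)) and "\n" not in str(document):
        path = Path(document)
        sep = delimiter or ("\t" if path.suffix.lower() == ".tsv" else ",")
        name = collection or path.stem
        buf: object = path
    else:
        sep = delimiter or ","
        name = collection or "collection"
        buf = io.StringIO(str(document))
    frame = pd.read_csv(buf, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    if id_column not in frame.columns:
        raise ValidationError(
            f"id column {id_column!r} not present; sheet columns: {list(frame.columns)}"
        )
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sid = str(row[id_column]).strip()
        if not sid:
            raise ValidationError("empty subject identifier in sheet")
        if sid in seen:
            raise DuplicateError(f"duplicate subject id {sid!r}")
        seen.add(sid)
        values = {c: str(row[c]) for c in frame.columns if c != id_column}
        records.append(SubjectRecord(collection=name, subject_id=sid, raw_values=values))
    return records


def transform_collection(
    records: list[SubjectRecord],
    rules: list[MappingRule],
    patterns: dict[str, RepresentationPattern],
    ontology: OntologyIndex,
) -> tuple[TripleSet, TransformReport]:
    """Harmonize one collection's records into subject-centric triples.

    Every record contributes its subject/collection/identifier triples;
    each rule-covered, non-missing, mapped cell instantiates the rule's
    pattern.  A mapped class IRI absent from the loaded ontology is a hard
    consistency error; unmapped tokens and missing cells are only tallied.
    """
    from .errors import ConsistencyError

    if not records:
        return TripleSet(), TransformReport(collection="")
    name = records[0].collection
    for r in records:
        if r.collection != name:
            raise UsageError("records from multiple collections passed in one call")
    for rule in rules:
        if rule.collection != name:
            raise ValidationError(
                f"rule for collection {rule.collection!r} applied to {name!r}"
            )
        if rule.pattern_id not in patterns:
            raise ValidationError(f"rule references unknown pattern {rule.pattern_id!r}")
    columns = set()
    for r in records:
        columns.update(r.raw_values)
    for rule in rules:
        if rule.source_column not in columns:
            raise ValidationError(
                f"rule references unknown column {rule.source_column!r} in {name!r}"
            )

    out = TripleSet()
    report = TransformReport(collection=name, n_rows=len(records))
    coll_node = collection_node(name)
    out.add((coll_node, RDF.type, COLLECTION))
    out.add((coll_node, RDFS.label, Literal(name)))

    for record in records:
        subj = subject_node(name, record.subject_id)
        out.add((subj, RDF.type, SUBJECT))
        out.add((subj, SUBJECT_IDENTIFIER, Literal(record.subject_id)))
        out.add((subj, MEMBER_OF_COLLECTION, coll_node))
        for rule in rules:
            raw = record.raw_values.get(rule.source_column, "")
            resolved = resolve_value(rule, raw)
            if resolved is MISSING:
                report.missing[rule.source_column] = (
                    report.missing.get(rule.source_column, 0) + 1
                )
                continue
            if isinstance(resolved, Unmapped):
                col_tokens = report.unmapped.setdefault(rule.source_column, {})
                col_tokens[resolved.token] = col_tokens.get(resolved.token, 0) + 1
                continue
            pattern = patterns[rule.pattern_id]
            if not rule.numeric and str(resolved) not in ontology:
                raise ConsistencyError(
                    f"rule for {name}/{rule.source_column!r} maps to term "
                    f"{resolved!r} absent from the ontology"
                )
            report.mapped_cells += 1
            for triple in pattern.instantiate(subj, name, record.subject_id, resolved):
                out.add(triple)
    report.n_triples = len(out)
    return out, report


def merge_graphs(parts: list[TripleSet]) -> TripleSet:
    """Set union of triple sets (duplicates collapse)."""
    merged: set[Triple] = set()
    for p in parts:
        merged |= p.triples
    return TripleSet(merged)


def _to_rdflib_graph(triples: TripleSet) -> Graph:
    g = Graph()
    for t in triples:
        g.add(t)
    return g


def serialize_graph(triples: TripleSet, format: str = "ntriples") -> str:
    """Serialize to Turtle or canonical (line-sorted) N-Triples text."""
    if format in ("ntriples", "nt"):
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in triples
        )
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "turtle":
        return _to_rdflib_graph(triples).serialize(format="turtle")
    raise UsageError(f"unknown serialization format {format!r}")


def load_triples(document: str | Path, format: str | None = None) -> TripleSet:
    """Parse a Turtle/N-Triples document back into a TripleSet."""
    g = Graph()
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).is_file()
    ):
        g.parse(location=str(document), format=format or ("nt" if str(document).endswith(".nt") else "turtle"))
    else:
        g.parse(data=str(document), format=format or "turtle")
    return TripleSet(set(g))
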