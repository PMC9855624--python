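"""Cohort state: set algebra over per-criterion subject-ID sets.

A cohort is defined by inclusion and exclusion criteria.  Each criterion
resolves — through the knowledge graph — to a set of subject ids; the
cohort is the intersection of all inclusion sets (all subjects when there
are none) minus the union of all exclusion sets.

Exclusion removes only subjects *known* to have the excluded value: a
subject whose stage is missing from the source data survives an
"exclude stage I" criterion.  This differs from complement semantics and
is deliberate — absence of evidence is not evidence of absence.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from urllib.parse import parse_qsl, urlencode, urlparse, urlunparse

from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from .errors import UsageError, ValidationError
from .kgstore import (
    CLASS_FEATURES,
    KnowledgeGraph,
    NUMERIC_FEATURES,
    _feature_values,
    subjects_by_class,
    subjects_by_number,
)
from .namespaces import APP, SUBJECT
from .ontology import TermId

#: feature columns shown in previews and CSV exports, in display order
EXPORT_FEATURES = ("sex", "age", "disease_type", "tumor_site", "stage")


@dataclass
class CohortCriterion:
    """One inclusion or exclusion filter.

    Class criteria carry one or more ontology terms (multi-select union);
    numeric criteria carry bounds.  ``expand`` applies sub-term /
    partonomic expansion to class criteria.
    """

    polarity: str  # "inclusion" | "exclusion"
    kind: str  # "class" | "numeric"
    feature: str
    terms: list[TermId] = field(default_factory=list)
    low: float | None = None
    high: float | None = None
    low_strict: bool = False
    high_strict: bool = False
    expand: bool = True

    def validate(self) -> None:
        if self.polarity not in ("inclusion", "exclusion"):
            raise ValidationError(f"bad polarity {self.polarity!r}")
        if self.kind == "class":
            if self.feature not in CLASS_FEATURES:
                raise ValidationError(f"{self.feature!r} is not a class feature")
            if not self.terms:
                raise ValidationError("class criterion needs at least one term")
        elif self.kind == "numeric":
            if self.feature not in NUMERIC_FEATURES:
                raise ValidationError(f"{self.feature!r} is not a numeric feature")
            if self.low is None and self.high is None:
                raise ValidationError("numeric criterion needs at least one bound")
        else:
            raise ValidationError(f"bad criterion kind {self.kind!r}")


@dataclass
class CohortState:
    criteria: list[CohortCriterion] = field(default_factory=list)
    per_criterion_sets: list[set[str]] = field(default_factory=list)
    cohort: set[str] = field(default_factory=set)


def resolve_criterion(graph: KnowledgeGraph, criterion: CohortCriterion) -> set[str]:
    """Subject-ID set for one criterion (union over its terms)."""
    criterion.validate()
    if criterion.kind == "numeric":
        return subjects_by_number(
            graph,
            criterion.feature,
            low=criterion.low,
            high=criterion.high,
            low_strict=criterion.low_strict,
            high_strict=criterion.high_strict,
        )
    out: set[str] = set()
    for term in criterion.terms:
        out |= subjects_by_class(graph, criterion.feature, term, expand=criterion.expand)
    return out


def combine(graph: KnowledgeGraph, criteria: list[CohortCriterion]) -> CohortState:
    """Resolve all criteria and apply the cohort formula.

    cohort = (∩ inclusion sets) \\ (∪ exclusion sets); with no inclusion
    criteria the base set is every subject in the repository.
    """
    state = CohortState(criteria=list(criteria))
    cohort: set[str] | None = None
    excluded: set[str] = set()
    for criterion in criteria:
        s = resolve_criterion(graph, criterion)
        state.per_criterion_sets.append(s)
        if criterion.polarity == "inclusion":
            cohort = s if cohort is None else cohort & s
        else:
            excluded |= s
    if cohort is None:
        cohort = graph.all_subject_ids()
    state.cohort = cohort - excluded
    return state


def term_counts(
    graph: KnowledgeGraph,
    feature: str,
    terms: list[TermId],
    expand: bool = True,
) -> dict[TermId, int]:
    """Per-term subject counts backing the count bars next to a search box."""
    return {
        term: len(subjects_by_class(graph, feature, term, expand=expand))
        for term in terms
    }


def _subject_table(graph: KnowledgeGraph, subject_ids: list[str]) -> list[dict[str, str]]:
    """Feature labels per subject; missing values render as empty cells."""
    values: dict[str, dict[str, list]] = {f: {} for f in EXPORT_FEATURES}
    for feature in EXPORT_FEATURES:
        for sid, value in _feature_values(graph, feature, asserted_only=True):
            values[feature].setdefault(sid, []).append(value)
    rows = []
    for sid in subject_ids:
        row = {
            "collection": graph.subject_collection.get(sid, ""),
            "subject_id": sid,
        }
        for feature in EXPORT_FEATURES:
            vals = values[feature].get(sid, [])
            rendered = sorted(
                str(v.toPython()) if isinstance(v, Literal) else graph.ontology.label(str(v))
                for v in vals
            )
            row[feature] = "; ".join(rendered)
        rows.append(row)
    return rows


def preview(
    graph: KnowledgeGraph, cohort: set[str], seed: int = 0, sample_size: int = 10
) -> list[dict[str, str]]:
    """A reproducible random sample of at most ``sample_size`` subjects.

    Cohorts at or under the sample size are returned in full.  Columns:
    collection, subject id, then the curated feature labels, with missing
    values as empty cells.
    """
    ids = sorted(cohort)
    if len(ids) > sample_size:
        ids = sorted(random.Random(seed).sample(ids, sample_size))
    return _subject_table(graph, ids)


def export_csv(graph: KnowledgeGraph, cohort: set[str]) -> str:
    """RFC 4180 CSV of the full cohort, one row per member.

    Cell values are ontology labels (not IRIs); rows are sorted by
    (collection, subject id); line endings are LF.
    """
    ids = sorted(cohort)
    rows = _subject_table(graph, ids)
    rows.sort(key=lambda r: (r["collection"], r["subject_id"]))
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf,
        fieldnames=["collection", "subject_id", *EXPORT_FEATURES],
        lineterminator="\n",
    )
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def repository_summary(graph: KnowledgeGraph) -> tuple[int, int, int]:
    """(subject count, collection count, unique concept count).

    Concepts are the distinct ontology classes asserted as types of
    instance data — asserted only, so inference-expanded ancestors do not
    inflate the number.
    """
    subjects = 0
    collections = 0
    concepts: set[str] = set()
    for s, p, o in graph.asserted:
        if p != RDF.type:
            continue
        if o == SUBJECT:
            subjects += 1
        elif o == APP.Collection:
            collections += 1
        elif isinstance(o, URIRef) and str(o) in graph.ontology:
            concepts.add(str(o))
    return subjects, collections, len(concepts)


@dataclass(frozen=True)
class ViewerHandoff:
    """Image-viewer hand-off URL plus its length for oversize detection."""

    url: str
    length: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.url


def viewer_handoff_url(
    base_url: str, cohort: set[str], param: str = "subject"
) -> ViewerHandoff:
    """Build the viewer URL carrying every cohort subject id.

    Ids are sorted and percent-encoded as repeated query parameters; the
    parameter name is configurable because viewers differ.
    """
    if not cohort:
        raise UsageError("cannot build a viewer URL for an empty cohort")
    parsed = urlparse(base_url)
    if not parsed.scheme or not parsed.netloc:
        raise UsageError(f"base URL {base_url!r} is not an absolute URL")
    query = parse_qsl(parsed.query, keep_blank_values=True)
    query.extend((param, sid) for sid in sorted(cohort))
    url = urlunparse(parsed._replace(query=urlencode(query, doseq=False)))
    return ViewerHandoff(url=url, length=len(url))
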