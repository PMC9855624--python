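"""Data catalog: standardized labels for clinical data elements and a
per-collection presence matrix.

The catalog does not itself carry semantics; it inventories which curated
elements exist in which collections and guides mapping-rule authoring.
Documents are YAML (see ``data/catalog.yaml`` for the shipped fixture
catalog and its schema).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DuplicateError, ValidationError

VALUE_KINDS = frozenset({"categorical", "numeric", "identifier", "free_text"})

_SNAKE = re.compile(r"[^a-z0-9]+")


def normalize_label(label: str) -> str:
    """Lowercase snake_case normalization applied to standard labels."""
    return _SNAKE.sub("_", label.strip().lower()).strip("_")


@dataclass
class CollectionDescriptor:
    name: str
    description: str = ""
    subject_count: int = 0


@dataclass
class CatalogElement:
    standard_label: str
    description: str
    value_kind: str
    collections_present: set[str] = field(default_factory=set)


@dataclass
class Catalog:
    elements: dict[str, CatalogElement] = field(default_factory=dict)
    collections: list[CollectionDescriptor] = field(default_factory=list)

    def collection_names(self) -> list[str]:
        return [c.name for c in self.collections]


def load_catalog(document: str | Path) -> Catalog:
    """Load and validate a catalog document (YAML text or path)."""
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).is_file()
    ):
        raw = Path(document).read_text(encoding="utf-8")
    else:
        raw = str(document)
    try:
        doc = yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed catalog document: {exc}") from exc

    collections = [
        CollectionDescriptor(
            name=str(c["name"]),
            description=str(c.get("description", "")),
            subject_count=int(c.get("subject_count", 0)),
        )
        for c in doc.get("collections", []) or []
    ]
    known = {c.name for c in collections}
    if len(known) != len(collections):
        raise DuplicateError("duplicate collection name in catalog")

    catalog = Catalog(collections=collections)
    offenders: list[str] = []
    for e in doc.get("elements", []) or []:
        label = normalize_label(str(e["standard_label"]))
        kind = str(e.get("value_kind", "categorical"))
        if kind not in VALUE_KINDS:
            raise ValidationError(
                f"element {label!r}: value_kind {kind!r} not in {sorted(VALUE_KINDS)}"
            )
        if label in catalog.elements:
            raise DuplicateError(f"duplicate standard_label {label!r}")
        present = {str(c) for c in e.get("collections_present", []) or []}
        offenders.extend(f"{label} -> {c}" for c in sorted(present - known))
        catalog.elements[label] = CatalogElement(
            standard_label=label,
            description=str(e.get("description", "")),
            value_kind=kind,
            collections_present=present,
        )
    if offenders:
        raise ValidationError(
            "elements reference unknown collections: " + "; ".join(offenders)
        )
    return catalog


def coverage_matrix(catalog: Catalog) -> pd.DataFrame:
    """Boolean presence table: rows = collections, columns = standard labels.

    Both axes are sorted alphabetically, so the matrix is deterministic and
    invariant under element insertion order.
    """
    rows = sorted(c.name for c in catalog.collections)
    cols = sorted(catalog.elements)
    data = {
        label: [catalog.elements[label].collections_present.__contains__(r) for r in rows]
        for label in cols
    }
    return pd.DataFrame(data, index=rows, columns=cols, dtype=bool)
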