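"""Representation patterns and mapping rules.

A :class:`RepresentationPattern` is a small graph template with slots;
instantiating it per table row yields the RDF statements expressing one
clinical fact (a diagnosis, a tumor location, a demographic attribute, a
clinical stage).  A :class:`MappingRule` binds one source column of one
collection to a pattern and translates that collection's value dialect
(e.g. the token ``"ID"`` in a breast-collection ``Cancer type`` column
standing for invasive ductal carcinoma) into ontology term IRIs or typed
literals.

Node identifiers are minted deterministically from
``(collection, subject id, pattern id, slot)`` so that re-running a
transformation reproduces the graph byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote

import yaml
from rdflib import Literal, URIRef
from rdflib.namespace import XSD

from .errors import DuplicateError, ValidationError
from .namespaces import DATA, PREFIXES, expand_curie


class _Missing:
    """Singleton marker for an empty / not-available source value."""

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "MISSING"


MISSING = _Missing()

#: Default tokens treated as missing values, case-insensitive.
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "n/a", "unknown", "not available"})


@dataclass(frozen=True)
class Unmapped:
    """A non-empty token the rule's value map could not translate."""

    token: str


@dataclass(frozen=True)
class Slot:
    name: str
    kind: str  # "node" | "class" | "literal"
    datatype: URIRef | None = None


@dataclass
class RepresentationPattern:
    pattern_id: str
    slots: dict[str, Slot]
    #: template triples; each position is a Slot name (str starting with "$")
    #: or a resolved URIRef constant
    template_triples: list[tuple[object, URIRef, object]]
    description: str = ""

    @property
    def value_slot(self) -> Slot | None:
        """The single class- or literal-valued slot a rule fills, if any."""
        for s in self.slots.values():
            if s.kind in ("class", "literal"):
                return s
        return None

    def instantiate(
        self, subject_node: URIRef, collection: str, subject_id: str, value
    ) -> list[tuple[URIRef, URIRef, object]]:
        """Fill slots for one row and return the resulting triples.

        ``value`` fills the pattern's class slot (a term IRI string) or
        literal slot (a number); node slots are minted deterministically.
        """
        bindings: dict[str, object] = {"subject": subject_node}
        for slot in self.slots.values():
            if slot.kind == "node":
                bindings[slot.name] = mint_instance_iri(
                    collection, subject_id, self.pattern_id, slot.name
                )
            elif slot.kind == "class":
                bindings[slot.name] = URIRef(str(value))
            else:  # literal
                bindings[slot.name] = Literal(value, datatype=slot.datatype)
        def fill(term):
            # slot refs are plain "$name" strings; URIRef is also a str
            # subclass, so test the marker, not the type
            if isinstance(term, str) and not isinstance(term, URIRef) and term.startswith("$"):
                return bindings[term[1:]]
            return term

        return [(fill(s), p, fill(o)) for s, p, o in self.template_triples]


def mint_instance_iri(collection: str, subject_id: str, *extra: str) -> URIRef:
    """Deterministic, collision-free instance IRI under the data namespace."""
    parts = [quote(p, safe="") for p in (collection, subject_id, *extra)]
    return URIRef(str(DATA) + "/".join(parts))


@dataclass
class MappingRule:
    collection: str
    source_column: str
    catalog_element: str
    pattern_id: str
    value_map: dict[str, str] = field(default_factory=dict)  # token -> term IRI
    numeric: bool = False
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS


@dataclass
class RuleSet:
    rules: list[MappingRule]
    id_columns: dict[str, str] = field(default_factory=dict)  # collection -> id column

    def for_collection(self, collection: str) -> list[MappingRule]:
        return [r for r in self.rules if r.collection == collection]


def _read_document(document: str | Path) -> dict:
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).is_file()
    ):
        raw = Path(document).read_text(encoding="utf-8")
    else:
        raw = str(document)
    try:
        return yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed config document: {exc}") from exc


def load_patterns(document: str | Path) -> dict[str, RepresentationPattern]:
    """Load and validate a pattern repository (YAML text or path)."""
    doc = _read_document(document)
    prefixes = dict(PREFIXES)
    prefixes.update({str(k): str(v) for k, v in (doc.get("prefixes") or {}).items()})

    repo: dict[str, RepresentationPattern] = {}
    for entry in doc.get("patterns", []) or []:
        pid = str(entry["id"])
        if pid in repo:
            raise DuplicateError(f"duplicate pattern id {pid!r}")
        slots: dict[str, Slot] = {}
        for name, kind in (entry.get("slots") or {}).items():
            kind = str(kind)
            if kind == "node" or kind == "class":
                slots[str(name)] = Slot(str(name), kind)
            elif kind.startswith("literal"):
                _, _, dt = kind.partition(":")
                datatype = URIRef(str(XSD) + dt) if dt else XSD.string
                slots[str(name)] = Slot(str(name), "literal", datatype)
            else:
                raise ValidationError(f"pattern {pid!r}: unknown slot kind {kind!r}")
        triples_raw = entry.get("triples") or []
        if not triples_raw:
            raise ValidationError(f"pattern {pid!r}: empty template")
        template: list[tuple[object, URIRef, object]] = []
        for t in triples_raw:
            if len(t) != 3:
                raise ValidationError(f"pattern {pid!r}: template triple must have 3 terms")
            s, p, o = (str(x) for x in t)

            def term(tok: str, position: str):
                if tok.startswith("$"):
                    name = tok[1:]
                    if name != "subject" and name not in slots:
                        raise ValidationError(
                            f"pattern {pid!r}: slot {name!r} referenced but not declared"
                        )
                    return tok
                return URIRef(expand_curie(tok, prefixes))

            p_term = term(p, "predicate")
            if not isinstance(p_term, URIRef):
                raise ValidationError(f"pattern {pid!r}: predicate cannot be a slot")
            template.append((term(s, "subject"), p_term, term(o, "object")))
        value_slots = [s for s in slots.values() if s.kind in ("class", "literal")]
        if len(value_slots) > 1:
            raise ValidationError(f"pattern {pid!r}: more than one value slot")
        repo[pid] = RepresentationPattern(
            pattern_id=pid,
            slots=slots,
            template_triples=template,
            description=str(entry.get("description", "")).strip(),
        )
    return repo


def load_rules(
    document: str | Path, patterns: dict[str, RepresentationPattern]
) -> RuleSet:
    """Load mapping rules, validating pattern references and value maps."""
    doc = _read_document(document)
    prefixes = dict(PREFIXES)
    prefixes.update({str(k): str(v) for k, v in (doc.get("prefixes") or {}).items()})
    missing = frozenset(
        str(t).casefold() for t in doc.get("missing_tokens", sorted(DEFAULT_MISSING_TOKENS))
    )
    id_columns = {
        str(name): str(cfg["id_column"])
        for name, cfg in (doc.get("collections") or {}).items()
    }
    rules: list[MappingRule] = []
    seen: set[tuple[str, str]] = set()
    for entry in doc.get("rules", []) or []:
        pid = str(entry["pattern"])
        if pid not in patterns:
            raise ValidationError(f"rule references unknown pattern {pid!r}")
        numeric = bool(entry.get("numeric", False))
        value_map = {
            str(k).strip().casefold(): expand_curie(str(v), prefixes)
            for k, v in (entry.get("value_map") or {}).items()
        }
        if numeric and value_map:
            raise ValidationError("numeric rule must not carry a value_map")
        if not numeric and not value_map:
            raise ValidationError(
                f"rule for column {entry.get('source_column')!r} needs a value_map"
            )
        slot = patterns[pid].value_slot
        if slot is None:
            raise ValidationError(f"pattern {pid!r} has no value slot for a rule to fill")
        if numeric != (slot.kind == "literal"):
            raise ValidationError(
                f"rule/pattern mismatch for {pid!r}: numeric={numeric} "
                f"but value slot kind is {slot.kind!r}"
            )
        key = (str(entry["collection"]), str(entry["source_column"]))
        if key in seen:
            raise DuplicateError(f"duplicate rule for {key}")
        seen.add(key)
        rules.append(
            MappingRule(
                collection=key[0],
                source_column=key[1],
                catalog_element=str(entry.get("catalog_element", "")),
                pattern_id=pid,
                value_map=value_map,
                numeric=numeric,
                missing_tokens=missing,
            )
        )
    return RuleSet(rules=rules, id_columns=id_columns)


def resolve_value(rule: MappingRule, raw: str):
    """Translate one raw cell through the rule's value dialect.

    Returns a term IRI string (class rules), an ``int``/``float`` (numeric
    rules), :data:`MISSING` for missing-value tokens, or an
    :class:`Unmapped` marker for tokens the dialect does not cover.
    Deterministic and idempotent under re-trimming.
    """
    token = "" if raw is None else str(raw).strip()
    if token.casefold() in rule.missing_tokens:
        return MISSING
    if rule.numeric:
        try:
            value = float(token)
        except ValueError:
            return Unmapped(token)
        return int(value) if value.is_integer() else value
    mapped = rule.value_map.get(token.casefold())
    if mapped is None:
        return Unmapped(token)
    return mapped
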