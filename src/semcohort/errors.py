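"""Exception hierarchy shared across the package."""

from __future__ import annotations


class SemcohortError(Exception):
    """Base class for all package-specific errors."""


class OntologyParseError(SemcohortError):
    """An ontology document could not be parsed as RDF."""


class CycleError(SemcohortError):
    """A cycle was found in a relation that must be acyclic.

    ``cycle`` holds the offending IRI path (first element repeated last).
    """

    def __init__(self, relation: str, cycle: list[str]):
        self.relation = relation
        self.cycle = cycle
        super().__init__(f"cycle in {relation}: {' -> '.join(cycle)}")


class NotFoundError(SemcohortError):
    """A term, subject, or resource was requested but does not exist."""


class ValidationError(SemcohortError):
    """A config document or domain object violates its invariants."""


class DuplicateError(ValidationError):
    """A unique identifier occurred more than once."""


class ConsistencyError(SemcohortError):
    """Instance data references a class unknown to the loaded ontology."""


class UsageError(SemcohortError):
    """An operation was called with arguments outside its contract."""
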