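"""Stateless REST layer over the knowledge graph and cohort operations.

The application is a plain WSGI callable (serve it with any WSGI server,
e.g. ``wsgiref.simple_server``), so it carries no web-framework
dependency.  Every request carries all state needed to answer it — cohort
criteria travel in the request body — which keeps responses reproducible
and lets identical requests be processed in parallel.

Single-criterion resolution is a GET (mirroring per-filter-element
calls); cohort-wide operations are POSTs with the full criteria list in
the body, because long criteria lists would overflow URL length limits.
Errors are problem-details JSON with machine-readable codes.
"""

from __future__ import annotations

import json
from urllib.parse import parse_qsl

from .catalog import Catalog, coverage_matrix
from .cohort import (
    CohortCriterion,
    combine,
    export_csv,
    preview,
    repository_summary,
    resolve_criterion,
    viewer_handoff_url,
)
from .errors import NotFoundError, SemcohortError, UsageError, ValidationError
from .kgstore import CLASS_FEATURES, KnowledgeGraph, NUMERIC_FEATURES
from .ontology import search_terms

_JSON = [("Content-Type", "application/json; charset=utf-8")]
_CSV = [
    ("Content-Type", "text/csv; charset=utf-8"),
    ("Content-Disposition", "attachment; filename=cohort.csv"),
]

_CRITERION_SCHEMA = {
    "polarity": "inclusion|exclusion",
    "kind": "class|numeric",
    "feature": f"one of {list(CLASS_FEATURES + NUMERIC_FEATURES)}",
    "terms": "[term IRI, ...] (class kind)",
    "low/high": "numbers (numeric kind)",
    "low_strict/high_strict": "booleans",
    "expand": "boolean, default true",
}

#: endpoint table driving both routing and the discovery document
ENDPOINTS = [
    {
        "path": "/",
        "method": "GET",
        "description": "Discovery document listing every available endpoint.",
        "parameters": {},
    },
    {
        "path": "/summary",
        "method": "GET",
        "description": "Repository overview: subject, collection and unique concept counts.",
        "parameters": {},
    },
    {
        "path": "/collections",
        "method": "GET",
        "description": "Collections with description, subject count and element availability flags.",
        "parameters": {},
    },
    {
        "path": "/terms/search",
        "method": "GET",
        "description": "Criterion text search over term labels, synonyms and definitions.",
        "parameters": {"q": "search text (non-empty)"},
    },
    {
        "path": "/subjects",
        "method": "GET",
        "description": "Subject ids matching one encoded criterion; no filters returns all subjects.",
        "parameters": {
            "feature": f"one of {list(CLASS_FEATURES + NUMERIC_FEATURES)}",
            "term": "term IRI (repeatable, class features)",
            "expand": "true|false (default true)",
            "low": "number", "high": "number",
            "low_strict": "true|false", "high_strict": "true|false",
        },
    },
    {
        "path": "/cohort/count",
        "method": "POST",
        "description": "Combined cohort size for a criteria list.",
        "parameters": {"body": {"criteria": [_CRITERION_SCHEMA]}},
    },
    {
        "path": "/cohort/preview",
        "method": "POST",
        "description": "Seeded random sample of at most 10 cohort members with feature labels.",
        "parameters": {"body": {"criteria": [_CRITERION_SCHEMA], "seed": "integer"}},
    },
    {
        "path": "/cohort/csv",
        "method": "POST",
        "description": "CSV export of the full cohort (header + one row per member).",
        "parameters": {"body": {"criteria": [_CRITERION_SCHEMA]}},
    },
    {
        "path": "/cohort/viewer-url",
        "method": "POST",
        "description": "Image-viewer hand-off URL carrying all cohort subject ids.",
        "parameters": {
            "body": {
                "criteria": [_CRITERION_SCHEMA],
                "base_url": "absolute viewer URL",
                "param": "query parameter name (default 'subject')",
            }
        },
    },
]


def _dumps(obj) -> bytes:
    return (json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n").encode("utf-8")


def _problem(status: int, code: str, detail: str):
    return status, _JSON, _dumps({"status": status, "code": code, "detail": detail})


def criterion_from_dict(doc: dict) -> CohortCriterion:
    """Build and validate a criterion from its JSON representation."""
    if not isinstance(doc, dict):
        raise ValidationError("criterion must be an object")
    crit = CohortCriterion(
        polarity=str(doc.get("polarity", "inclusion")),
        kind=str(doc.get("kind", "class")),
        feature=str(doc.get("feature", "")),
        terms=[str(t) for t in doc.get("terms", [])],
        low=doc.get("low"),
        high=doc.get("high"),
        low_strict=bool(doc.get("low_strict", False)),
        high_strict=bool(doc.get("high_strict", False)),
        expand=bool(doc.get("expand", True)),
    )
    crit.validate()
    return crit


def create_app(graph: KnowledgeGraph, catalog: Catalog | None = None):
    """Build the WSGI application bound to a knowledge graph."""

    def handle(method: str, path: str, query: list[tuple[str, str]], body: dict):
        if path == "/" and method == "GET":
            return 200, _JSON, _dumps({"endpoints": ENDPOINTS})

        if path == "/summary" and method == "GET":
            subjects, collections, concepts = repository_summary(graph)
            return 200, _JSON, _dumps(
                {"subjects": subjects, "collections": collections, "unique_concepts": concepts}
            )

        if path == "/collections" and method == "GET":
            counts: dict[str, int] = {}
            for sid, coll in graph.subject_collection.items():
                counts[coll] = counts.get(coll, 0) + 1
            flags = {}
            descriptions = {}
            if catalog is not None:
                matrix = coverage_matrix(catalog)
                flags = {name: matrix.loc[name].to_dict() for name in matrix.index}
                descriptions = {c.name: c.description for c in catalog.collections}
            rows = [
                {
                    "name": name,
                    "description": descriptions.get(name, ""),
                    "subject_count": counts.get(name, 0),
                    "elements": flags.get(name, {}),
                }
                for name in sorted(set(counts) | set(flags))
            ]
            return 200, _JSON, _dumps({"collections": rows})

        if path == "/terms/search" and method == "GET":
            params = dict(query)
            q = params.get("q", "").strip()
            if not q:
                return _problem(400, "empty-query", "parameter 'q' must be non-empty")
            hits = [
                {
                    "term": tid,
                    "label": label,
                    "matched_field": field,
                    "definition": graph.ontology.terms[tid].definition,
                }
                for tid, label, field in search_terms(graph.ontology, q)
            ]
            return 200, _JSON, _dumps({"query": q, "results": hits})

        if path == "/subjects" and method == "GET":
            params = dict(query)
            if not params:
                return 200, _JSON, _dumps({"subjects": sorted(graph.all_subject_ids())})
            feature = params.get("feature", "")
            terms = [v for k, v in query if k == "term"]
            doc = {
                "feature": feature,
                "kind": "numeric" if feature in NUMERIC_FEATURES else "class",
                "terms": terms,
                "expand": params.get("expand", "true").lower() != "false",
                "low_strict": params.get("low_strict", "").lower() == "true",
                "high_strict": params.get("high_strict", "").lower() == "true",
            }
            for bound in ("low", "high"):
                if bound in params:
                    try:
                        doc[bound] = float(params[bound])
                    except ValueError:
                        return _problem(400, "bad-bound", f"{bound} must be numeric")
            crit = criterion_from_dict(doc)
            return 200, _JSON, _dumps({"subjects": sorted(resolve_criterion(graph, crit))})

        if path.startswith("/cohort/") and method == "POST":
            criteria = [criterion_from_dict(c) for c in body.get("criteria", [])]
            state = combine(graph, criteria)
            if path == "/cohort/count":
                return 200, _JSON, _dumps({"count": len(state.cohort)})
            if path == "/cohort/preview":
                seed = int(body.get("seed", 0))
                return 200, _JSON, _dumps(
                    {"count": len(state.cohort), "rows": preview(graph, state.cohort, seed=seed)}
                )
            if path == "/cohort/csv":
                return 200, _CSV, export_csv(graph, state.cohort).encode("utf-8")
            if path == "/cohort/viewer-url":
                handoff = viewer_handoff_url(
                    str(body.get("base_url", "")),
                    state.cohort,
                    param=str(body.get("param", "subject")),
                )
                return 200, _JSON, _dumps({"url": handoff.url, "length": handoff.length})

        return _problem(404, "no-such-endpoint", f"{method} {path} is not a known endpoint")

    def app(environ, start_response):
        method = environ.get("REQUEST_METHOD", "GET").upper()
        path = environ.get("PATH_INFO", "/") or "/"
        query = parse_qsl(environ.get("QUERY_STRING", ""), keep_blank_values=True)
        body: dict = {}
        if method == "POST":
            try:
                length = int(environ.get("CONTENT_LENGTH") or 0)
                raw = environ["wsgi.input"].read(length) if length else b"{}"
                body = json.loads(raw.decode("utf-8") or "{}")
            except (ValueError, KeyError):
                status, headers, payload = _problem(400, "bad-json", "request body is not valid JSON")
                start_response(f"{status} ERROR", headers)
                return [payload]
        try:
            status, headers, payload = handle(method, path, query, body)
        except NotFoundError as exc:
            status, headers, payload = _problem(404, "not-found", str(exc))
        except (ValidationError, UsageError) as exc:
            status, headers, payload = _problem(400, "invalid-request", str(exc))
        except SemcohortError as exc:
            status, headers, payload = _problem(500, "internal-error", str(exc))
        reason = {200: "OK", 400: "Bad Request", 404: "Not Found", 500: "Internal Server Error"}
        start_response(f"{status} {reason.get(status, 'Error')}", headers)
        return [payload]

    return app


def call(app, method: str, path: str, query: str = "", body: dict | None = None):
    """In-process request helper: returns (status code, headers, body bytes)."""
    import io

    raw = json.dumps(body or {}).encode("utf-8")
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "CONTENT_LENGTH": str(len(raw)),
        "wsgi.input": io.BytesIO(raw),
    }
    captured: dict = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])
        captured["headers"] = headers

    chunks = app(environ, start_response)
    return captured["status"], captured["headers"], b"".join(chunks)
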