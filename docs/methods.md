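# Methods

## The representation model

Each row of a collection sheet is treated as a set of declarative
statements about one subject, not as tagged cells. The transformation
instantiates small graph templates ("representation patterns") per row:

- **diagnosis** — `subject —has_diagnosis→ dx ; dx a obo:OGMS_0000073 ;
  dx —IAO:0000136 (is about)→ disease ; disease a <mapped class>`
- **tumor_site** — `subject —has_finding→ tumor ; tumor a obo:NCIT_C3262 ;
  tumor —RO:0001025 (located in)→ site ; site a <mapped class>`
- **sex** — `subject —RO:0000086 (has quality)→ q ; q a <PATO class>`
- **clinical_stage** — `subject —has_stage→ st ; st a <NCIT-style stage class>`
- **age** — `subject —age_years→ "<int>"^^xsd:integer`

Subject, collection and identifier triples use a small application
vocabulary (`app:` namespace). Instance IRIs are minted deterministically
from `(collection, subject id, pattern id, slot)` with percent-encoding,
so repeated runs produce byte-identical canonical N-Triples. The shipped
patterns are this package's own reconstructions of common clinical
representation shapes; they are deliberately minimal (single value slot
per pattern, one rule per `(collection, column)`), which keeps mapping
rules declarative and cross-column conditional logic out of scope.

Age is stored as integer years. The reference "above age 60" criterion is
strict (`> 60`); both strict and non-strict bounds are supported on
either side.

## Ontology handling and closures

Ontology modules are parsed with rdflib from Turtle or N-Triples. `part
of` edges are accepted both as plain `obo:BFO_0000050` object triples and
as OWL existential restrictions (`subClassOf [onProperty part_of;
someValuesFrom X]`); both normalize to a direct edge. Terms lacking an
`rdfs:label` fall back to their IRI local name so search never silently
drops a term. Definitions come from the IAO textual-definition annotation
with `rdfs:comment` as fallback; synonyms from the oboInOwl synonym
annotations participate in criterion text search and are flagged in the
result's `matched_field`.

Closures over `subClassOf` and `part of` are reflexive-free transitive
closures computed by memoized depth-first search; `descendants` and
`parts_of` re-add the query term at the query layer. Cycles (including
self-loops) are hard errors that report the offending path — the intended
inputs are DAGs, and tolerating a cycle would silently corrupt every
downstream expansion.

## Inference

Inference is forward-materialized once at store construction, to a
fixpoint, rather than backward-chained at query time — answers are then
stateless and repeatable, and at catalog scale materialization is cheap.
Two rules:

1. **Taxonomic type propagation.** An instance typed `C` is inferred
   typed every strict ancestor of `C`. A lung-adenocarcinoma disease
   instance is thereby found by a lung-cancer query.
2. **Partonomic location propagation.** For every `tumor located_in
   site` with `site a C`, the tumor is inferred `located_in` the class
   IRI of `C` and of every transitive whole of `C` (class IRIs are punned
   as region referents, since no instance nodes exist for the wholes). A
   tumor asserted in the epiglottic vallecula is thereby found by a
   tumor-in-neck query.

The inferred set is kept disjoint from the asserted set. Repository
overview numbers count **asserted** types only — counting
inference-expanded ancestors would inflate the "unique concepts" figure
meaninglessly.

Criterion resolution (`subjects_by_class`) deliberately does **not** rely
on rule 1: it expands the criterion term at the query layer (term +
subclass descendants, plus transitive parts for anatomical sites) and
matches asserted values. This keeps `expand=False` a true exact-class
filter and makes expanded retrieval provably the union of exact
retrievals.

## Query building

Queries are assembled in three parts: a header (prefix table + `SELECT
DISTINCT` line), one basic-graph-pattern block per attribute clause (each
clause introduces fresh bind variables named after its alias), and the
filter clauses (`=`, `IN`, and numeric comparisons). The supported
surface is conjunctive patterns with value filters — enough for every
cohort operation; `OPTIONAL`/`UNION`/property paths are out of scope. The
emitted text is valid SPARQL, and the test suite executes it with
rdflib's SPARQL engine as an independent second path: for every spec in
the suite the external engine and the native matcher must return
identical binding sets.

## Cohort semantics

`cohort = (∩ inclusion sets) \ (∪ exclusion sets)`; with no inclusion
criteria the base set is every subject. Multi-term criteria union their
per-term sets. Exclusion removes only subjects with an asserted matching
value: a subject whose stage is absent from the source sheet is *not*
removed by a stage exclusion, because the repository only knows what the
sheets said. This differs from set-complement semantics and is the main
behavioral subtlety of the module; numeric filters likewise never match
subjects missing the feature.

Previews sample uniformly without replacement with a caller-supplied
seed (default sample size 10; smaller cohorts are returned whole). CSV
export is RFC 4180, UTF-8, LF, rows sorted by (collection, subject id),
cells holding ontology labels with missing values as empty cells. The
viewer hand-off URL carries sorted, percent-encoded subject ids as
repeated query parameters; the parameter name is configurable because the
target viewer's contract is deployment-specific, and the URL length is
returned so callers can detect oversize hand-offs.

## REST layer

The API is a plain WSGI callable with no framework dependency. It is
stateless by construction: cohort criteria travel in each request body,
responses are canonical JSON (sorted keys), and repeated identical
requests return byte-identical bodies. The root endpoint serves a
discovery document generated from the same table that drives routing, so
new endpoints appear in discovery without client changes. Single-criterion
resolution is a GET; cohort-wide operations are POSTs because long
criteria lists would overflow URL limits. Errors are problem-details
JSON with machine-readable codes (400 malformed, 404 unknown
term/endpoint).

## The synthetic repository

The generator emits four collections (60 + 60 + 40 + 40 = 200 subjects):
two lung collections sharing a vocabulary but differing in both column
names (`Cancer Type` vs `Dx`) and value dialects (`Lung Adenocarcinoma`
vs `adeno`), a breast collection using two-letter diagnosis codes (`ID`,
`IL`), and a head-and-neck collection whose anatomic sites include the
epiglottic vallecula, tongue and larynx. Stage is drawn from a six-value
distribution weighted toward mid stages; ages are uniform on 40–85; sex
is balanced except in the breast collection (95% female). Per-column
missingness defaults to 15% for stage, 10% for site, 5% for age, 2% for
sex, 0 for diagnosis — enough missing stage data to exercise the
exclusion semantics without dominating the sheets. One collection carries
an extra uncurated column to mirror single-collection oddities.

Ground truth is sampled first; dialect rendering and then missingness are
applied afterward, so the truth retains values the sheet lost. The
independent oracle (`oracle_cohort`) evaluates criteria by brute-force
row scan over the *observed* truth values with its own closure-expansion
code; it shares no code path with the store or the cohort algebra.

What passing tests do not show: the generator draws attributes
independently, so nothing is verified about realistic clinical
correlations, free-text noise beyond the fixed dialect tokens,
multi-valued cells, or catalog-scale (hundreds of elements) performance.
The mini-ontology modules are hand-authored fixture-scale reconstructions
(identifiers are illustrative), not extracts of released ontologies.

## Problem sizes and numerical choices

The shipped study conditions are the 4-collection / 200-subject
repository, 100 randomized criteria sets for oracle-equivalence checks,
and 200-node random DAGs for closure stress tests. Determinism choices
throughout: canonical (line-sorted) N-Triples, sorted query bindings,
sorted CSV rows, seeded sampling, and sorted JSON keys in API responses.
Numeric cell parsing accepts integers and decimal floats; integral floats
collapse to `int` so `"63.0"` and `"63"` agree. Missing-value tokens are
`{"", "NA", "N/A", "unknown", "not available"}` case-insensitive,
overridable per rules document.

## Known limitations

- No OWL-DL reasoning, consistency checking, or named-graph management;
  inference is exactly the two rules above.
- The in-memory store indexes by predicate only; it is sized for
  fixture-to-catalog scale, not millions of triples.
- Provenance of transformations lives in the JSON report files, not in
  the graph.
- The external-SPARQL-endpoint adapter surface is limited to the
  generated query text being valid SPARQL; no HTTP client is included.
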