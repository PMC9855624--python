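# semcohort

Clinical data sheets attached to medical-imaging collections are a rich
source of subject-level information — diagnoses, tumor locations,
demographics, stage — but they arrive as heterogeneous delimited files:
the same element is called `Dx` in one collection and `Cancer type` in
another, and a breast-cancer sheet may encode *invasive ductal carcinoma*
as the bare token `ID`. `semcohort` harmonizes such tables into an
ontology-aligned RDF knowledge graph and serves cross-collection cohort
search over it.

The stack, bottom to top:

- **catalog** — standardized labels for data elements and a per-collection
  presence matrix.
- **ontology** — loads OBO-style modules (Turtle/N-Triples), indexes term
  labels/definitions/synonyms, and materializes transitive closures over
  `subClassOf` and `part of` (both the plain-triple and the OWL
  existential-restriction dialect are accepted).
- **patterns** — graph templates with slots (diagnosis, tumor anatomical
  location, sex, age, clinical stage) plus per-column mapping rules that
  translate each collection's value dialect into term IRIs or typed
  literals.
- **transform** — applies rules and patterns row by row, minting
  deterministic instance IRIs and reporting unmapped/missing cells.
- **kgstore** — the merged graph with forward-materialized inference:
  instances typed *C* are inferred typed every ancestor of *C*, and a
  tumor located in the *epiglottic vallecula* is inferred located in the
  *throat* and the *neck* via the `part of` closure. Queries are built in
  three parts (prefixes + SELECT, one graph-pattern block per attribute,
  then filters); the emitted text is valid SPARQL, and a native
  conjunctive matcher evaluates the same spec in-process.
- **cohort** — set algebra over per-criterion subject-ID sets:
  `cohort = (∩ inclusions) \ (∪ exclusions)`, with sub-term expansion
  (excluding *stage I* also excludes *stage IA*) and
  missing-data-retaining exclusion semantics (a subject with no stage
  recorded is **not** removed by a stage exclusion). Previews, RFC 4180
  CSV export, repository summaries, and image-viewer hand-off URLs.
- **api** — a stateless WSGI REST layer (discovery document, term search,
  per-criterion subject resolution, cohort preview/CSV/count/viewer-URL).
- **fixtures** — a seeded synthetic four-collection repository
  (~200 subjects) with known ground truth and an independent brute-force
  cohort oracle.

## Worked example

```python
from semcohort.fixtures import generate_repository, FixtureSpec
import semcohort.fixtures as fx
from semcohort.pipeline import harmonize_repository
from semcohort.cohort import CohortCriterion, combine, preview, repository_summary

repo = generate_repository(FixtureSpec(seed=7))        # synthetic sheets + configs
store, reports, ontology = harmonize_repository(repo)  # transform + inference

subjects, collections, concepts = repository_summary(store)
print(f"repository: {subjects} subjects, {collections} collections, "
      f"{concepts} unique concepts")

criteria = [
    CohortCriterion("inclusion", "class", "sex", [fx.MALE]),
    CohortCriterion("inclusion", "numeric", "age", low=60, low_strict=True),
    CohortCriterion("inclusion", "class", "disease_type", [fx.LUNG_AD]),
    CohortCriterion("exclusion", "class", "stage", [fx.STAGE_I]),
]
state = combine(store, criteria)
print(f"cohort: {len(state.cohort)} subjects")
print(preview(store, state.cohort, seed=3)[0])
```

prints

```
repository: 200 subjects, 4 collections, 23 unique concepts
cohort: 12 subjects
{'collection': 'LUNG-A', 'subject_id': 'LA-014', 'sex': 'male', 'age': '61',
 'disease_type': 'lung adenocarcinoma', 'tumor_site': 'lung', 'stage': 'stage III'}
```

The 12 subjects are the male subjects above age 60 with lung
adenocarcinoma who are not *known* to have stage I (or IA/IB) disease;
subjects with missing stage data remain. The same cohort falls out of the
independent row-scan oracle over the generator's ground truth.

The same flow is available from the shell:

```sh
semcohort fixtures generate --seed 7 --out fixdir
semcohort transform --sheet fixdir/LUNG-A.csv --collection LUNG-A \
    --id-column "Patient ID" --rules fixdir/rules.yaml \
    --patterns fixdir/patterns.yaml \
    --ontology fixdir/anatomy.ttl --ontology fixdir/disease.ttl \
    --ontology fixdir/clinical.ttl --out LUNG-A.nt --report LUNG-A.json
semcohort cohort --graph LUNG-A.nt \
    --ontology fixdir/anatomy.ttl --ontology fixdir/disease.ttl \
    --ontology fixdir/clinical.ttl \
    --include disease_type=obo:DOID_3910 --include age\>60 \
    --csv cohort.csv --preview --seed 3
semcohort serve --graph LUNG-A.nt --ontology fixdir/clinical.ttl ... --port 8000
```

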