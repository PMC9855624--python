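"""Synthetic repository generator with known ground truth.

Emulates the heterogeneity of real collection sheets: the same catalog
element appears under different column names and value dialects in
different collections (one lung collection says ``Cancer Type: Lung
Adenocarcinoma``, the other says ``Dx: adeno``; a breast collection
encodes invasive ductal carcinoma as the bare token ``ID``).

Ground truth is sampled first and then rendered through the dialect maps;
missingness is applied to the rendered sheet only, so the truth retains
the value while the sheet loses it.  That separation is what makes the
"exclude subjects *known* to have stage I disease" semantics testable:
the oracle sees which values were observable, exactly like the pipeline.

The module also provides an independent brute-force cohort oracle
(:func:`oracle_cohort`) implemented directly over truth rows — it shares
no code path with the knowledge-graph store or the cohort algebra.

What the generator does *not* emulate: realistic clinical marginals or
correlations between attributes (age, stage and disease are sampled
independently), free-text noise beyond the fixed dialect tokens, and
multi-valued cells.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .cohort import CohortCriterion
from .errors import ValidationError
from .ontology import OntologyIndex, TermId, load_ontology

_OBO = "http://purl.obolibrary.org/obo/"


def obo(local: str) -> str:
    return _OBO + local


# disease / site / sex / stage vocabulary used by the authored mini-ontology
LUNG_AD = obo("DOID_3910")
LUNG_LCC = obo("DOID_4556")
LUNG_SCC = obo("DOID_3907")
IDC = obo("DOID_3008")
ILC = obo("DOID_3856")
HNSCC = obo("DOID_5520")
LUNG_CANCER = obo("DOID_1324")
BREAST_CANCER = obo("DOID_1612")
CANCER = obo("DOID_162")

NECK = obo("UBERON_0000974")
THROAT = obo("UBERON_0000341")
VALLECULA = obo("UBERON_0013165")
LARYNX = obo("UBERON_0001737")
TONGUE = obo("UBERON_0001723")
MOUTH = obo("UBERON_0000165")
LUNG = obo("UBERON_0002048")
RUL = obo("UBERON_0002170")
RLL = obo("UBERON_0002171")
BREAST = obo("UBERON_0000310")

MALE = obo("PATO_0000384")
FEMALE = obo("PATO_0000383")

STAGE = obo("NCIT_C28108")
STAGE_I = obo("NCIT_C27966")
STAGE_IA = obo("NCIT_C27975")
STAGE_IB = obo("NCIT_C27976")
STAGE_II = obo("NCIT_C28054")
STAGE_III = obo("NCIT_C27970")
STAGE_IV = obo("NCIT_C27971")

FEATURE_ORDER = ("diagnosis", "site", "sex", "age", "stage")

#: column-name and value dialects per collection style; ``renders`` maps a
#: ground-truth term to the token the sheet prints, and the mapping rules
#: carry the inverse.
STYLES: dict[str, dict] = {
    "full-names": {
        "id_column": "Patient ID",
        "columns": {
            "diagnosis": "Cancer Type",
            "site": "Primary Site",
            "sex": "Gender",
            "age": "Age",
            "stage": "Stage",
        },
        "renders": {
            "diagnosis": {
                LUNG_AD: "Lung Adenocarcinoma",
                LUNG_LCC: "Lung Large Cell Carcinoma",
                LUNG_SCC: "Lung Squamous Cell Carcinoma",
            },
            "site": {
                RUL: "Upper Lobe of Right Lung",
                RLL: "Lower Lobe of Right Lung",
                LUNG: "Lung",
            },
            "sex": {MALE: "Male", FEMALE: "Female"},
            "stage": {
                STAGE_I: "Stage I",
                STAGE_IA: "Stage IA",
                STAGE_IB: "Stage IB",
                STAGE_II: "Stage II",
                STAGE_III: "Stage III",
                STAGE_IV: "Stage IV",
            },
        },
        "missing_token": "",
    },
    "abbreviated": {
        "id_column": "subject_id",
        "columns": {
            "diagnosis": "Dx",
            "site": "tumor_location",
            "sex": "sex",
            "age": "age_at_dx",
            "stage": "tumor_stage",
        },
        "renders": {
            "diagnosis": {LUNG_AD: "adeno", LUNG_LCC: "LCC", LUNG_SCC: "SCC"},
            "site": {RUL: "RUL", RLL: "RLL", LUNG: "lung"},
            "sex": {MALE: "M", FEMALE: "F"},
            "stage": {
                STAGE_I: "i",
                STAGE_IA: "ia",
                STAGE_IB: "ib",
                STAGE_II: "ii",
                STAGE_III: "iii",
                STAGE_IV: "iv",
            },
        },
        "missing_token": "NA",
    },
    "breast-codes": {
        "id_column": "Subject",
        "columns": {
            "diagnosis": "Cancer type",
            "site": "Tumor Site",
            "sex": "Sex",
            "age": "Age at Diagnosis",
            "stage": "AJCC Stage",
        },
        "renders": {
            "diagnosis": {IDC: "ID", ILC: "IL"},
            "site": {BREAST: "Breast"},
            "sex": {MALE: "M", FEMALE: "F"},
            "stage": {
                STAGE_I: "I",
                STAGE_IA: "IA",
                STAGE_IB: "IB",
                STAGE_II: "II",
                STAGE_III: "III",
                STAGE_IV: "IV",
            },
        },
        "missing_token": "",
    },
    "head-neck": {
        "id_column": "case_id",
        "columns": {
            "diagnosis": "Diagnosis",
            "site": "Anatomic Site",
            "sex": "Sex",
            "age": "Age",
            "stage": "Clinical Stage",
        },
        "renders": {
            "diagnosis": {HNSCC: "HNSCC"},
            "site": {
                VALLECULA: "epiglottic vallecula",
                TONGUE: "tongue",
                LARYNX: "larynx",
            },
            "sex": {MALE: "M", FEMALE: "F"},
            "stage": {
                STAGE_I: "I",
                STAGE_IA: "IA",
                STAGE_IB: "IB",
                STAGE_II: "II",
                STAGE_III: "III",
                STAGE_IV: "IV",
            },
        },
        "missing_token": "",
        "extra_columns": {"Mold or Dust Allergy": ["Y", "N"]},
    },
}

_STAGE_POOL = [
    (STAGE_I, 0.10),
    (STAGE_IA, 0.15),
    (STAGE_IB, 0.10),
    (STAGE_II, 0.25),
    (STAGE_III, 0.25),
    (STAGE_IV, 0.15),
]

DEFAULT_MISSINGNESS = {"diagnosis": 0.0, "site": 0.10, "sex": 0.02, "age": 0.05, "stage": 0.15}


@dataclass
class CollectionSpec:
    name: str
    n_subjects: int
    style: str
    id_prefix: str
    sex_weights: tuple[float, float] = (0.5, 0.5)  # (male, female)
    age_range: tuple[int, int] = (40, 85)
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValidationError("n_subjects must be non-negative")
        if self.style not in STYLES:
            raise ValidationError(f"unknown style {self.style!r}")
        for feature, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"missingness rate for {feature!r} outside [0,1]")


@dataclass
class FixtureSpec:
    seed: int = 7
    collections: list[CollectionSpec] = field(default_factory=lambda: default_collections())

    def validate(self) -> None:
        for c in self.collections:
            c.validate()


def default_collections() -> list[CollectionSpec]:
    return [
        CollectionSpec("LUNG-A", 60, "full-names", "LA-"),
        CollectionSpec("LUNG-B", 60, "abbreviated", "LB-"),
        CollectionSpec("BREAST-1", 40, "breast-codes", "BR-", sex_weights=(0.05, 0.95)),
        CollectionSpec("HN-1", 40, "head-neck", "HN-", sex_weights=(0.7, 0.3)),
    ]


@dataclass
class TruthRow:
    """Ground-truth attributes of one subject plus sheet observability."""

    collection: str
    subject_id: str
    values: dict[str, tuple[object, bool]]  # feature -> (true value, observed on sheet)

    def observed(self, feature: str):
        value, is_observed = self.values[feature]
        return value if is_observed else None


FixtureTruth = list[TruthRow]


@dataclass
class FixtureRepository:
    spec: FixtureSpec
    sheets: dict[str, str]  # collection name -> CSV text
    rules_yaml: str
    patterns_yaml: str
    catalog_yaml: str
    ontology_docs: dict[str, str]  # filename -> Turtle text
    truth: FixtureTruth


def _data_text(name: str) -> str:
    return resources.files("semcohort.data").joinpath(name).read_text(encoding="utf-8")


def ontology_documents() -> dict[str, str]:
    """The authored mini-ontology modules shipped with the package."""
    return {n: _data_text(n) for n in ("anatomy.ttl", "disease.ttl", "clinical.ttl")}


def load_fixture_ontology() -> OntologyIndex:
    return load_ontology(*ontology_documents().values())


def _weighted_choice(rng: random.Random, pool: list[tuple[str, float]]) -> str:
    terms = [t for t, _ in pool]
    weights = [w for _, w in pool]
    return rng.choices(terms, weights=weights, k=1)[0]


def _disease_pool(style: str) -> list[tuple[str, float]]:
    renders = STYLES[style]["renders"]["diagnosis"]
    if LUNG_AD in renders:
        return [(LUNG_AD, 0.5), (LUNG_LCC, 0.25), (LUNG_SCC, 0.25)]
    if IDC in renders:
        return [(IDC, 0.7), (ILC, 0.3)]
    return [(HNSCC, 1.0)]


def _site_pool(style: str) -> list[tuple[str, float]]:
    renders = STYLES[style]["renders"]["site"]
    terms = sorted(renders)
    return [(t, 1.0) for t in terms]


def generate_repository(spec: FixtureSpec | None = None) -> FixtureRepository:
    """Generate sheets, mapping rules, configs, ontology docs and truth.

    Deterministic for a given spec seed: regeneration is byte-identical.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = random.Random(spec.seed)

    truth: FixtureTruth = []
    sheets: dict[str, str] = {}
    rules_doc: dict = {
        "prefixes": {"obo": _OBO},
        "collections": {},
        "rules": [],
    }

    for cspec in spec.collections:
        style = STYLES[cspec.style]
        rules_doc["collections"][cspec.name] = {"id_column": style["id_column"]}
        columns = style["columns"]
        renders = style["renders"]
        missing_token = style["missing_token"]

        # mapping rules: inverse of the render dialect
        pattern_by_feature = {
            "diagnosis": "diagnosis",
            "site": "tumor_site",
            "sex": "sex",
            "stage": "clinical_stage",
        }
        for feature in ("diagnosis", "site", "sex", "stage"):
            rules_doc["rules"].append(
                {
                    "collection": cspec.name,
                    "source_column": columns[feature],
                    "catalog_element": {
                        "diagnosis": "diagnosis",
                        "site": "primary_tumor_site",
                        "sex": "sex",
                        "stage": "clinical_stage",
                    }[feature],
                    "pattern": pattern_by_feature[feature],
                    "value_map": {
                        token: "obo:" + term[len(_OBO):]
                        for term, token in renders[feature].items()
                    },
                }
            )
        rules_doc["rules"].append(
            {
                "collection": cspec.name,
                "source_column": columns["age"],
                "catalog_element": "age_at_diagnosis",
                "pattern": "age",
                "numeric": True,
            }
        )

        # ground truth, then rendering, then missingness
        disease_pool = _disease_pool(cspec.style)
        site_pool = _site_pool(cspec.style)
        width = max(3, len(str(cspec.n_subjects)))
        header = [style["id_column"]] + [columns[f] for f in FEATURE_ORDER]
        extras = style.get("extra_columns", {})
        header += sorted(extras)
        out_rows: list[list[str]] = []
        for i in range(cspec.n_subjects):
            sid = f"{cspec.id_prefix}{i + 1:0{width}d}"
            disease = _weighted_choice(rng, disease_pool)
            site = _weighted_choice(rng, site_pool)
            sex = rng.choices([MALE, FEMALE], weights=cspec.sex_weights, k=1)[0]
            age = rng.randint(*cspec.age_range)
            stage = _weighted_choice(rng, _STAGE_POOL)
            true_values = {"diagnosis": disease, "site": site, "sex": sex, "age": age, "stage": stage}
            row_cells = [sid]
            observed_flags: dict[str, bool] = {}
            for feature in FEATURE_ORDER:
                value = true_values[feature]
                token = str(value) if feature == "age" else renders[feature][value]
                rate = cspec.missingness.get(feature, 0.0)
                masked = rng.random() < rate
                observed_flags[feature] = not masked
                row_cells.append(missing_token if masked else token)
            for col in sorted(extras):
                row_cells.append(rng.choice(extras[col]))
            out_rows.append(row_cells)
            truth.append(
                TruthRow(
                    collection=cspec.name,
                    subject_id=sid,
                    values={f: (true_values[f], observed_flags[f]) for f in FEATURE_ORDER},
                )
            )
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(out_rows)
        sheets[cspec.name] = buf.getvalue()

    return FixtureRepository(
        spec=spec,
        sheets=sheets,
        rules_yaml=yaml.safe_dump(rules_doc, sort_keys=True),
        patterns_yaml=_data_text("patterns.yaml"),
        catalog_yaml=_data_text("catalog.yaml"),
        ontology_docs=ontology_documents(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle


def _oracle_expansion(
    ontology: OntologyIndex, feature: str, terms: list[TermId], expand: bool
) -> set[TermId]:
    """Criterion term expansion recomputed directly from the closure maps."""
    allowed = set(terms)
    if not expand:
        return allowed
    for term in terms:
        for t, ancestors in ontology.subclass_closure.items():
            if term in ancestors:
                allowed.add(t)
        if feature == "tumor_site":
            for t, wholes in ontology.partof_closure.items():
                if term in wholes:
                    allowed.add(t)
    return allowed


_FEATURE_TO_TRUTH = {
    "disease_type": "diagnosis",
    "tumor_site": "site",
    "sex": "sex",
    "stage": "stage",
    "age": "age",
}


def _row_matches(row: TruthRow, criterion: CohortCriterion, ontology: OntologyIndex) -> bool:
    value = row.observed(_FEATURE_TO_TRUTH[criterion.feature])
    if value is None:
        return False
    if criterion.kind == "numeric":
        if criterion.low is not None and (
            value <= criterion.low if criterion.low_strict else value < criterion.low
        ):
            return False
        if criterion.high is not None and (
            value >= criterion.high if criterion.high_strict else value > criterion.high
        ):
            return False
        return True
    allowed = _oracle_expansion(ontology, criterion.feature, criterion.terms, criterion.expand)
    return str(value) in allowed


def oracle_cohort(
    truth: FixtureTruth,
    criteria: list[CohortCriterion],
    ontology: OntologyIndex,
) -> set[str]:
    """Brute-force row scan over ground truth — the pipeline's oracle.

    Evaluates the same inclusion/exclusion algebra directly on truth rows
    (observed values only), with explicit closure expansion; it never
    touches the transformation, store, or cohort code paths.
    """
    include: set[str] | None = None
    exclude: set[str] = set()
    all_ids = {row.subject_id for row in truth}
    for criterion in criteria:
        criterion.validate()
        matched = {
            row.subject_id for row in truth if _row_matches(row, criterion, ontology)
        }
        if criterion.polarity == "inclusion":
            include = matched if include is None else include & matched
        else:
            exclude |= matched
    if include is None:
        include = all_ids
    return include - exclude


# ---------------------------------------------------------------------------
# randomized inputs for property tests


CRITERION_TERM_POOLS: dict[str, list[str]] = {
    "disease_type": [
        CANCER, LUNG_CANCER, LUNG_AD, LUNG_LCC, LUNG_SCC,
        BREAST_CANCER, IDC, ILC, HNSCC,
    ],
    "tumor_site": [NECK, THROAT, VALLECULA, LARYNX, TONGUE, MOUTH, LUNG, RUL, RLL, BREAST],
    "sex": [MALE, FEMALE],
    "stage": [STAGE, STAGE_I, STAGE_IA, STAGE_IB, STAGE_II, STAGE_III, STAGE_IV],
}


def random_criteria(rng: random.Random, max_criteria: int = 3) -> list[CohortCriterion]:
    """A random inclusion/exclusion criteria set over the fixture vocabulary."""
    criteria = []
    for _ in range(rng.randint(1, max_criteria)):
        polarity = "exclusion" if rng.random() < 0.3 else "inclusion"
        feature = rng.choice(["disease_type", "tumor_site", "sex", "stage", "age"])
        if feature == "age":
            low = rng.choice([None, rng.randint(40, 80)])
            high = rng.choice([None, rng.randint(50, 90)])
            if low is None and high is None:
                low = 60
            if low is not None and high is not None and low > high:
                low, high = high, low
            criteria.append(
                CohortCriterion(
                    polarity=polarity, kind="numeric", feature="age",
                    low=low, high=high,
                    low_strict=rng.random() < 0.5, high_strict=rng.random() < 0.5,
                )
            )
        else:
            pool = CRITERION_TERM_POOLS[feature]
            terms = rng.sample(pool, rng.randint(1, min(2, len(pool))))
            criteria.append(
                CohortCriterion(
                    polarity=polarity, kind="class", feature=feature,
                    terms=terms, expand=rng.random() < 0.8,
                )
            )
    return criteria


def random_ontology_document(
    seed: int, n_terms: int = 50, p_subclass: float = 0.06, p_partof: float = 0.04
) -> tuple[str, list[tuple[str, str]], list[tuple[str, str]]]:
    """A random DAG ontology in Turtle, plus its edge lists for oracles.

    Edges only point from higher-index to lower-index terms, so the graph
    is acyclic by construction.
    """
    rng = random.Random(seed)
    base = "https://w3id.org/semcohort/test/"
    iri = [f"{base}T{i}" for i in range(n_terms)]
    sub_edges: list[tuple[str, str]] = []
    part_edges: list[tuple[str, str]] = []
    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix obo: <http://purl.obolibrary.org/obo/> .",
    ]
    for i in range(n_terms):
        lines.append(f'<{iri[i]}> a owl:Class ; rdfs:label "term {i}" .')
        for j in range(i):
            if rng.random() < p_subclass:
                sub_edges.append((iri[i], iri[j]))
                lines.append(f"<{iri[i]}> rdfs:subClassOf <{iri[j]}> .")
            if rng.random() < p_partof:
                part_edges.append((iri[i], iri[j]))
                lines.append(f"<{iri[i]}> obo:BFO_0000050 <{iri[j]}> .")
    return "\n".join(lines) + "\n", sub_edges, part_edges
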