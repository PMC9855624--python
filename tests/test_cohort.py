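"""Cohort set algebra, previews, CSV export, summaries, viewer hand-off."""

from __future__ import annotations

import csv
import io
import random

import pytest

import semcohort.fixtures as fx
from semcohort.cohort import (
    CohortCriterion,
    combine,
    export_csv,
    preview,
    repository_summary,
    resolve_criterion,
    term_counts,
    viewer_handoff_url,
)
from semcohort.errors import UsageError
from semcohort.fixtures import oracle_cohort, random_criteria


def male_over_60_lung_ad_not_stage1() -> list[CohortCriterion]:
    """Male subjects above age 60 with lung adenocarcinoma, excluding
    stage I disease (sub-stages included)."""
    return [
        CohortCriterion("inclusion", "class", "sex", [fx.MALE]),
        CohortCriterion("inclusion", "numeric", "age", low=60, low_strict=True),
        CohortCriterion("inclusion", "class", "disease_type", [fx.LUNG_AD]),
        CohortCriterion("exclusion", "class", "stage", [fx.STAGE_I]),
    ]


class TestResolveAndCombine:
    def test_multi_term_union(self, store):
        crit = CohortCriterion(
            "inclusion", "class", "disease_type", [fx.LUNG_AD, fx.LUNG_LCC]
        )
        per_term = [
            resolve_criterion(store, CohortCriterion("inclusion", "class", "disease_type", [t]))
            for t in crit.terms
        ]
        assert resolve_criterion(store, crit) == per_term[0] | per_term[1]

    def test_reference_cohort_equals_table_oracle(self, repo, store, ontology):
        criteria = male_over_60_lung_ad_not_stage1()
        state = combine(store, criteria)
        assert state.cohort == oracle_cohort(repo.truth, criteria, ontology)
        assert len(state.cohort) > 0

    def test_no_criteria_returns_all_subjects(self, store):
        assert combine(store, []).cohort == store.all_subject_ids()

    def test_self_subtraction_empties_cohort(self, store):
        crit = [
            CohortCriterion("inclusion", "class", "sex", [fx.FEMALE]),
            CohortCriterion("exclusion", "class", "sex", [fx.FEMALE]),
        ]
        assert combine(store, crit).cohort == set()

    def test_exclusion_retains_stage_missing_subjects(self, repo, store):
        """Excluding stage I removes only subjects *known* to be stage I;
        subjects with missing stage data stay in the cohort."""
        state = combine(
            store, [CohortCriterion("exclusion", "class", "stage", [fx.STAGE_I])]
        )
        stage_missing = {t.subject_id for t in repo.truth if t.observed("stage") is None}
        stage1_known = {
            t.subject_id
            for t in repo.truth
            if t.observed("stage") in {fx.STAGE_I, fx.STAGE_IA, fx.STAGE_IB}
        }
        assert stage_missing and stage_missing <= state.cohort
        assert state.cohort.isdisjoint(stage1_known)

    def test_appending_criteria_never_enlarges(self, store):
        rng = random.Random(21)
        for _ in range(10):
            criteria = random_criteria(rng, max_criteria=4)
            running: list[CohortCriterion] = []
            prev = combine(store, running).cohort
            for crit in criteria:
                running.append(crit)
                cur = combine(store, running).cohort
                assert cur <= prev
                prev = cur

    def test_order_independence(self, store):
        rng = random.Random(22)
        for _ in range(10):
            criteria = random_criteria(rng, max_criteria=4)
            shuffled = criteria[:]
            rng.shuffle(shuffled)
            assert combine(store, criteria).cohort == combine(store, shuffled).cohort

    def test_reset_returns_base_set(self, store):
        narrowed = combine(store, male_over_60_lung_ad_not_stage1()).cohort
        assert narrowed < combine(store, []).cohort


class TestTermCounts:
    def test_counts_equal_enumeration(self, store):
        terms = [fx.LUNG_AD, fx.LUNG_LCC]
        counts = term_counts(store, "disease_type", terms)
        for t in terms:
            assert counts[t] == len(
                resolve_criterion(
                    store, CohortCriterion("inclusion", "class", "disease_type", [t])
                )
            )

    def test_term_with_no_subjects(self, store):
        assert term_counts(store, "tumor_site", [fx.MOUTH], expand=False) == {fx.MOUTH: 0}

    def test_counts_sum_at_least_union(self, store):
        terms = [fx.STAGE_I, fx.STAGE_IA]  # overlapping under expansion
        counts = term_counts(store, "stage", terms)
        union = resolve_criterion(
            store, CohortCriterion("inclusion", "class", "stage", terms)
        )
        assert sum(counts.values()) >= len(union)


class TestPreview:
    def test_oversize_cohort_sampled_to_ten(self, store):
        cohort = combine(store, []).cohort
        assert len(cohort) > 10
        rows = preview(store, cohort, seed=5)
        assert len(rows) == 10

    def test_small_cohort_returned_whole(self, store):
        three = set(sorted(store.all_subject_ids())[:3])
        assert len(preview(store, three, seed=5)) == 3

    def test_same_seed_identical(self, store):
        cohort = combine(store, []).cohort
        assert preview(store, cohort, seed=9) == preview(store, cohort, seed=9)

    def test_columns_and_missing_cells(self, repo, store):
        rows = preview(store, store.all_subject_ids(), seed=1)
        assert list(rows[0]) == [
            "collection", "subject_id", "sex", "age", "disease_type", "tumor_site", "stage",
        ]
        missing_ids = {t.subject_id for t in repo.truth if t.observed("stage") is None}
        sampled_missing = [r for r in rows if r["subject_id"] in missing_ids]
        for row in sampled_missing:
            assert row["stage"] == ""


class TestExportCsv:
    def test_line_count_is_members_plus_header(self, store):
        cohort = combine(store, male_over_60_lung_ad_not_stage1()).cohort
        text = export_csv(store, cohort)
        assert len(text.splitlines()) == len(cohort) + 1

    def test_empty_cohort_header_only(self, store):
        assert export_csv(store, set()).splitlines() == [
            "collection,subject_id,sex,age,disease_type,tumor_site,stage"
        ]

    def test_values_are_labels_not_iris(self, store):
        text = export_csv(store, store.all_subject_ids())
        assert "http" not in text
        assert "lung adenocarcinoma" in text

    def test_rows_sorted_and_missing_cells_empty(self, repo, store):
        text = export_csv(store, store.all_subject_ids())
        rows = list(csv.DictReader(io.StringIO(text)))
        keys = [(r["collection"], r["subject_id"]) for r in rows]
        assert keys == sorted(keys)
        missing = {t.subject_id for t in repo.truth if t.observed("stage") is None}
        assert missing
        for r in rows:
            if r["subject_id"] in missing:
                assert r["stage"] == ""


class TestSummary:
    def test_fixture_counts(self, repo, store):
        subjects, collections, concepts = repository_summary(store)
        assert subjects == len(repo.truth) == 200
        assert collections == len(repo.sheets) == 4
        observed_terms = {
            v
            for t in repo.truth
            for f in ("diagnosis", "site", "sex", "stage")
            if (v := t.observed(f)) is not None
        }
        # plus the fixed diagnosis/neoplasm classes every pattern instantiates
        assert concepts == len(observed_terms) + 2

    def test_empty_store(self, ontology):
        from semcohort.kgstore import build_store
        from semcohort.transform import TripleSet

        assert repository_summary(build_store([TripleSet()], ontology)) == (0, 0, 0)

    def test_duplicate_typing_leaves_concepts_unchanged(self, store, ontology):
        from semcohort.kgstore import build_store
        from semcohort.transform import TripleSet

        doubled = build_store(
            [TripleSet(set(store.asserted.triples))], ontology
        )
        assert repository_summary(doubled)[2] == repository_summary(store)[2]


class TestViewerHandoff:
    def test_two_ids(self):
        h = viewer_handoff_url("https://viewer.example/nbia", {"B-2", "A-1"})
        assert h.url == "https://viewer.example/nbia?subject=A-1&subject=B-2"
        assert h.length == len(h.url)

    def test_space_is_percent_encoded(self):
        h = viewer_handoff_url("https://viewer.example/nbia", {"A 1"})
        assert "A+1" in h.url or "A%201" in h.url

    def test_parameter_count_matches_cohort(self, store):
        cohort = set(sorted(store.all_subject_ids())[:51])
        h = viewer_handoff_url("https://viewer.example/nbia", cohort, param="pid")
        assert h.url.count("pid=") == 51

    def test_empty_cohort_rejected(self):
        with pytest.raises(UsageError):
            viewer_handoff_url("https://viewer.example/nbia", set())

    def test_relative_base_rejected(self):
        with pytest.raises(UsageError):
            viewer_handoff_url("/nbia", {"A"})
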