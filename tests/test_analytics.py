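import random
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from afp.analytics import (
    ConfusionCounts,
    Submission,
    agreement,
    confusion,
    dashboard_stats,
    diff_submission,
    jaccard,
    load_submissions,
    mean_added_removed,
    save_submissions,
)
from afp.classify import DataTypeLabel
from afp.corpus import EntityType, ValidationError
from afp.extraction import ExtractionResult, MentionCount
from afp.pipeline import NotificationRecord, RunReport, TriageDecision, TriageStatus

GENE = EntityType.GENE


def extraction(paper_id="P1", **per_type):
    """ExtractionResult with given included id lists, e.g. gene=('a','b')."""
    included = {}
    for name, ids in per_type.items():
        t = EntityType(name)
        included[t] = tuple(
            MentionCount(c, t, 0, 2) for c in sorted(ids)
        )
    return ExtractionResult(paper_id, included, included)


def submission(paper_id="P1", status="complete", flags=None, **per_type):
    return Submission(
        paper_id=paper_id,
        person_id="WBPerson1",
        status=status,
        final_entities={EntityType(k): frozenset(v) for k, v in per_type.items()},
        flag_answers=flags or {l: False for l in DataTypeLabel},
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"g1", "g2"}, {"g1", "g2"}, 1.0),
            ({"g1"}, {"g2"}, 0.0),
            ({"g1", "g2"}, {"g2", "g3"}, 1 / 3),
            (set(), set(), 1.0),  # nothing present on either side
            (set(), {"g1"}, 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    @given(
        a=st.sets(st.integers(0, 12), max_size=8),
        b=st.sets(st.integers(0, 12), max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_bounded_and_equality_iff_one(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)


class TestDiffSubmission:
    def test_identical_sets_no_changes(self):
        ext = extraction(gene=("a", "b"), allele=("x",))
        sub = submission(gene={"a", "b"}, allele={"x"})
        report = diff_submission(ext, sub)
        for t, d in report.per_type.items():
            assert d.added == d.removed == frozenset()
            assert d.jaccard == 1.0

    def test_added_and_removed(self):
        ext = extraction(gene=("a", "b", "c"))
        sub = submission(gene={"a", "b", "d"})
        d = diff_submission(ext, sub).per_type[GENE]
        assert d.added == {"d"}
        assert d.removed == {"c"}
        assert d.jaccard == pytest.approx(0.5)

    def test_both_empty_convention(self):
        d = diff_submission(extraction(), submission()).per_type[GENE]
        assert d.jaccard == 1.0

    def test_paper_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            diff_submission(extraction("P1"), submission("P2"))

    def test_diff_round_trip_reconstructs_final_sets(self):
        rng = random.Random(0)
        pool = [f"g{i}" for i in range(12)]
        for _ in range(50):
            machine = set(rng.sample(pool, rng.randrange(0, 8)))
            final = set(rng.sample(pool, rng.randrange(0, 8)))
            d = diff_submission(
                extraction(gene=tuple(machine)), submission(gene=final)
            ).per_type[GENE]
            assert (machine | d.added) - d.removed == final


class TestConfusionAgreement:
    def test_perfect_prediction(self):
        c = confusion([True, False, True], [True, False, True])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 1)
        assert tuple(agreement(c)) == pytest.approx((1.0, 1.0, 1.0))

    def test_all_false_positive(self):
        c = confusion([True] * 4, [False] * 4)
        assert c.fp == 4 and c.tp == c.fn == c.tn == 0

    def test_enumerated_pairs(self):
        predicted = [True, True, False, False, True, False, False, False, True, True]
        reference = [True, False, False, False, True, True, False, False, True, True]
        c = confusion(predicted, reference)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 1, 1, 4)
        assert tuple(agreement(c)) == pytest.approx((0.8, 0.8, 0.8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion([True], [True, False])

    def test_zero_denominator_yields_undefined_marker(self):
        a = agreement(ConfusionCounts(tp=0, fp=0, fn=2, tn=8))
        assert a.accuracy == pytest.approx(0.8)
        assert a.precision is None
        assert a.recall == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            agreement(ConfusionCounts())

    def test_self_agreement_is_perfect(self):
        for pattern in ([True], [True, False, True, True], [False, True]):
            a = agreement(confusion(pattern, pattern))
            assert a.accuracy == 1.0
            assert a.precision == 1.0
            assert a.recall == 1.0


class TestMeanAddedRemoved:
    def test_single_diff(self):
        ext = extraction(gene=("a", "b", "c"))
        sub = submission(gene={"a", "b", "d"})
        stats = mean_added_removed([diff_submission(ext, sub)], GENE)
        assert stats == pytest.approx((1.0, 1.0, 0.5))

    def test_all_perfect(self):
        diffs = [
            diff_submission(extraction(gene=("a",)), submission(gene={"a"}))
            for _ in range(3)
        ]
        assert mean_added_removed(diffs, GENE) == pytest.approx((0.0, 0.0, 1.0))

    def test_hand_mean_of_removed(self):
        d1 = diff_submission(extraction(gene=("a", "b")), submission(gene={"b"}))
        d2 = diff_submission(extraction(gene=("a", "b", "c")), submission(gene={"c"}))
        assert mean_added_removed([d1, d2], GENE)[1] == pytest.approx(1.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mean_added_removed([], GENE)


def make_report(n_processed, n_discarded=0, n_emailed=None, run_date=date(2019, 10, 2)):
    decisions = [
        TriageDecision(f"P{i}", TriageStatus.PROCESSED) for i in range(n_processed)
    ] + [
        TriageDecision(f"D{i}", TriageStatus.DISCARDED_NO_ENTITIES)
        for i in range(n_discarded)
    ]
    extractions = tuple(extraction(f"P{i}", gene=("g1",)) for i in range(n_processed))
    from afp.classify import DataTypeFlags

    flags = tuple(
        DataTypeFlags({l: (False, -1.0) for l in DataTypeLabel})
        for _ in range(n_processed)
    )
    n_emailed = n_processed if n_emailed is None else n_emailed
    notifications = tuple(
        NotificationRecord(
            paper_id=f"P{i}", email="a@x.org", person_id="W1",
            token=f"{i:032x}", sent_at=run_date,
        )
        for i in range(n_emailed)
    )
    return RunReport(
        run_date=run_date,
        decisions=tuple(decisions),
        extractions=extractions,
        flags=flags,
        notifications=notifications,
    )


class TestDashboardStats:
    def test_no_submissions_zero_response_rate(self):
        stats = dashboard_stats([make_report(5)], [])
        assert stats.response_rate == 0.0
        assert stats.n_complete == stats.n_partial == 0
        assert stats.mean_genes_per_nonempty_submission is None

    def test_response_rate_definition(self):
        report = make_report(10)
        subs = [
            submission("P0", gene={"g1"}),
            submission("P1", gene={"g1", "g2"}),
            submission("P2", status="partial"),
        ]
        stats = dashboard_stats([report], subs)
        assert stats.n_emailed == 10
        assert stats.n_complete == 2
        assert stats.n_partial == 1
        assert stats.response_rate == pytest.approx(0.2)

    def test_discards_counted_but_not_emailed(self):
        stats = dashboard_stats([make_report(4, n_discarded=3)], [])
        assert stats.n_processed == 4
        assert stats.n_discarded == 3
        assert stats.n_emailed == 4

    def test_mean_genes_over_nonempty_submissions(self):
        report = make_report(4)
        subs = [
            submission("P0", gene={"g1", "g2", "g3"}),
            submission("P1", gene={"g1"}),
            submission("P2"),  # empty gene list excluded from the mean
        ]
        stats = dashboard_stats([report], subs)
        assert stats.mean_genes_per_nonempty_submission == pytest.approx(2.0)

    def test_histograms_count_papers_per_entity_count(self):
        stats = dashboard_stats([make_report(3)], [])
        assert stats.entity_count_histograms[GENE] == {1: 3}

    def test_unknown_paper_id_rejected(self):
        with pytest.raises(ValidationError):
            dashboard_stats([make_report(2)], [submission("P99")])


class TestSubmissionModel:
    def test_complete_requires_all_flag_answers(self):
        with pytest.raises(ValidationError):
            Submission(
                paper_id="P1", person_id="W1", status="complete",
                final_entities={}, flag_answers={},
            )

    def test_partial_may_omit_answers(self):
        sub = Submission(
            paper_id="P1", person_id="W1", status="partial",
            final_entities={}, flag_answers={},
        )
        assert sub.status == "partial"

    def test_unknown_manual_category_rejected(self):
        with pytest.raises(ValidationError):
            Submission(
                paper_id="P1", person_id="W1", status="partial",
                final_entities={}, flag_answers={},
                manual_entities={"new_planets": ("x",)},
            )

    def test_json_round_trip(self, tmp_path):
        subs = [
            submission("P1", gene={"g1", "g2"}, allele={"a1"}),
            Submission(
                paper_id="P2", person_id="W2", status="partial",
                final_entities={GENE: frozenset({"g9"})},
                flag_answers={DataTypeLabel.RNAI_PHENOTYPE: True},
                manual_datatype_answers={"human_disease_model": True},
                manual_entities={"new_strains": ("XX1", "XX2")},
                comments="see figure 2",
            ),
        ]
        f = tmp_path / "subs.json"
        save_submissions(subs, f)
        assert load_submissions(f) == subs
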