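import random
import statistics

import pytest

from afp.classify import DataTypeLabel, tokenize
from afp.corpus import EntityType, LexiconEntry, ValidationError
from afp.extraction import MatchRuleSet, extract_entities
from afp.analytics import diff_submission, jaccard
from afp.synth import (
    SIGNAL_KEYWORDS,
    WORDS,
    ArticleSpec,
    PlantedEntity,
    SubmissionErrorModel,
    generate_article,
    generate_batch,
    generate_labeled_corpus,
    random_lexicons,
    simulate_submission,
)

from oracle_utils import oracle_entry_count

RNAI = DataTypeLabel.RNAI_PHENOTYPE


def gene(name="tir-9", cid="WBGene90000001", synonyms=()):
    return LexiconEntry(EntityType.GENE, cid, name, synonyms)


class TestGenerateArticle:
    def test_planted_counts_are_exact_by_oracle(self, rng):
        lexicons = random_lexicons(rng)
        rules = MatchRuleSet()
        articles, truth_counts, _ = generate_batch(rng, 30, lexicons)
        by_id = {
            t: {e.canonical_id: e for e in entries}
            for t, entries in lexicons.items()
        }
        for article in articles:
            for truth in truth_counts[article.paper_id]:
                entry = by_id[truth.entity_type][truth.canonical_id]
                assert oracle_entry_count(article.title, entry, rules) == truth.title_count
                assert (
                    oracle_entry_count(article.searchable_text, entry, rules)
                    == truth.text_count
                )

    def test_threshold_plant_flows_through_extraction(self, rng):
        lexicons = random_lexicons(rng)
        entry = lexicons[EntityType.ALLELE][0]
        spec = ArticleSpec(
            "P1", (PlantedEntity(entry, body_count=2),), seed=4
        )
        article, _, _ = generate_article(spec)
        result = extract_entities(article, lexicons)
        assert result.included_ids(EntityType.ALLELE) == {entry.canonical_id}

    def test_below_threshold_plant_excluded(self, rng):
        lexicons = random_lexicons(rng)
        entry = lexicons[EntityType.ALLELE][0]
        spec = ArticleSpec(
            "P1", (PlantedEntity(entry, body_count=1),), seed=4
        )
        article, _, _ = generate_article(spec)
        assert extract_entities(article, lexicons).included_ids(EntityType.ALLELE) == set()

    def test_fixed_seed_byte_identical(self, rng):
        lexicons = random_lexicons(rng)
        entry = lexicons[EntityType.GENE][0]
        spec = ArticleSpec(
            "P1",
            (PlantedEntity(entry, title_count=1, body_count=3),),
            datatype_signals={RNAI: (SIGNAL_KEYWORDS[RNAI], 2)},
            emails=("a@x.org",),
            seed=99,
        )
        a1, c1, f1 = generate_article(spec)
        a2, c2, f2 = generate_article(spec)
        assert a1 == a2 and c1 == c2 and f1 == f2

    def test_overlapping_planted_forms_rejected_before_generation(self):
        a = gene("abc-1", "WBGeneA")
        b = gene("abc-12", "WBGeneB")  # contains abc-1 as a prefix
        spec = ArticleSpec(
            "P1", (PlantedEntity(a, body_count=1), PlantedEntity(b, body_count=1))
        )
        with pytest.raises(ValidationError, match="overlap"):
            generate_article(spec)

    def test_truth_flags_reflect_signal_spec(self):
        spec = ArticleSpec(
            "P1",
            datatype_signals={RNAI: (SIGNAL_KEYWORDS[RNAI], 3)},
            seed=0,
        )
        article, _, flags = generate_article(spec)
        assert flags[RNAI] is True
        assert sum(flags.values()) == 1
        assert any(kw in article.body for kw in SIGNAL_KEYWORDS[RNAI])

    def test_emails_preserve_order(self):
        spec = ArticleSpec("P1", emails=("z@a.org", "a@z.org"), seed=1)
        article, _, _ = generate_article(spec)
        assert article.body.index("z@a.org") < article.body.index("a@z.org")

    def test_word_list_is_clean(self):
        # distractors must never collide with signal keywords
        signal = {kw for kws in SIGNAL_KEYWORDS.values() for kw in kws}
        assert not signal & set(WORDS)
        assert all(w.isalpha() and w.islower() for w in WORDS)


class TestLabeledCorpus:
    def test_prob_one_every_positive_has_signal(self):
        corpus = generate_labeled_corpus(50, 50, RNAI, 1.0, seed=0)
        keywords = set(SIGNAL_KEYWORDS[RNAI])
        for article, labels in corpus.records:
            tokens = set(tokenize(article.body))
            if labels[RNAI]:
                assert tokens & keywords
            else:
                assert not tokens & keywords

    def test_prob_zero_no_signal_anywhere(self):
        corpus = generate_labeled_corpus(30, 30, RNAI, 0.0, seed=1)
        keywords = set(SIGNAL_KEYWORDS[RNAI])
        for article, _ in corpus.records:
            assert not set(tokenize(article.body)) & keywords

    def test_all_eight_labels_recorded(self):
        corpus = generate_labeled_corpus(2, 2, RNAI, 1.0, seed=2)
        for _, labels in corpus.records:
            assert set(labels) == set(DataTypeLabel)


def ten_gene_extraction(i):
    from afp.extraction import ExtractionResult, MentionCount

    mentions = tuple(
        MentionCount(f"g{i}-{k}", EntityType.GENE, 0, 3) for k in range(10)
    )
    return ExtractionResult(f"P{i}", {EntityType.GENE: mentions},
                            {EntityType.GENE: mentions})


class TestSimulateSubmission:
    FLAGS = {l: False for l in DataTypeLabel}

    def test_zero_error_model_is_identity(self):
        ext = ten_gene_extraction(0)
        sub, edits = simulate_submission(ext, self.FLAGS, SubmissionErrorModel())
        d = diff_submission(ext, sub).per_type[EntityType.GENE]
        assert d.jaccard == 1.0 and not d.added and not d.removed
        assert not edits.flipped

    def test_total_removal_gives_zero_jaccard(self):
        ext = ten_gene_extraction(0)
        model = SubmissionErrorModel(removal_prob=1.0)
        sub, _ = simulate_submission(ext, self.FLAGS, model)
        d = diff_submission(ext, sub).per_type[EntityType.GENE]
        assert d.jaccard == 0.0
        assert len(d.removed) == 10

    def test_removal_rate_recovered_within_three_se(self):
        p, k, n = 0.2, 10, 1000
        model = SubmissionErrorModel(removal_prob=p)
        rng = random.Random(123)
        removed_counts = []
        for i in range(n):
            ext = ten_gene_extraction(i)
            sub, _ = simulate_submission(ext, self.FLAGS, model, rng=rng)
            removed_counts.append(
                len(diff_submission(ext, sub).per_type[EntityType.GENE].removed)
            )
        mean = statistics.fmean(removed_counts)
        se = (k * p * (1 - p) / n) ** 0.5
        assert abs(mean - k * p) <= 3 * se

    def test_additions_come_from_unextracted_lexicon_entries(self, rng):
        lexicons = random_lexicons(rng)
        ids = {e.canonical_id for e in lexicons[EntityType.GENE]}
        from afp.extraction import ExtractionResult, MentionCount

        some = sorted(ids)[:3]
        mentions = tuple(MentionCount(c, EntityType.GENE, 0, 3) for c in some)
        ext = ExtractionResult("P1", {EntityType.GENE: mentions},
                               {EntityType.GENE: mentions})
        model = SubmissionErrorModel(addition_prob=1.0)
        sub, edits = simulate_submission(ext, self.FLAGS, model, lexicons)
        assert edits.added[EntityType.GENE] == ids - set(some)
        assert sub.final_entities[EntityType.GENE] == ids

    def test_flag_flips_recorded(self):
        model = SubmissionErrorModel(flag_flip_prob=1.0)
        sub, edits = simulate_submission(
            ten_gene_extraction(0), self.FLAGS, model
        )
        assert edits.flipped == frozenset(DataTypeLabel)
        assert all(sub.flag_answers[l] is True for l in DataTypeLabel)

    def test_manual_entities_drawn_at_rate(self):
        model = SubmissionErrorModel(manual_entity_rate=2.0, seed=5)
        sub, _ = simulate_submission(ten_gene_extraction(0), self.FLAGS, model)
        total = sum(len(v) for v in sub.manual_entities.values())
        assert total > 0

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            SubmissionErrorModel(removal_prob=1.5)
        with pytest.raises(ValidationError):
            SubmissionErrorModel(flag_flip_prob=-0.1)
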