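"""Synthetic articles, corpora, registries and submissions with ground truth.

Every downstream module is tested against corpora generated here: articles
are streams of distractor tokens with entity surface forms planted a known
number of times in title and body, data-type signal keywords inserted at
controlled rates, and email addresses placed in a known order.  Planted
forms follow community nomenclature shapes (gene ``abc-1``, allele
``sy53``, strain ``CB1417``, transgene ``syIs107``, species binomials), so
the hyphen/digit boundary rules are exercised realistically.

Exactness guarantee: a generated article contains each planted surface
form exactly the requested number of boundary-valid times.  This holds
because (i) tokens are space separated, (ii) the distractor vocabulary is
filtered so that no planted form (nor any synonym, protein-case variant,
abbreviated binomial or species alias of a planted entry) is a substring
of any distractor, signal keyword or other planted entry's forms.  Specs
violating the substring-exclusion rule are rejected before generation.

Author submissions are simulated with independent per-entity error
processes: each extracted entity is dropped with a removal probability,
unextracted lexicon entries are added with an addition probability, and
data-type flags are flipped with a flip probability; the exact edits are
returned alongside the submission so agreement metrics can be validated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import DataTypeLabel, LabeledCorpus
from .corpus import Article, EntityType, LexiconEntry, ValidationError
from .extraction import DEFAULT_SPECIES_ALIASES, ExtractionResult, MentionCount
from .analytics import MANUAL_ENTITY_CATEGORIES, Submission

__all__ = [
    "WORDS",
    "SIGNAL_KEYWORDS",
    "SPECIES_POOL",
    "PlantedEntity",
    "ArticleSpec",
    "SubmissionErrorModel",
    "EditRecord",
    "generate_article",
    "generate_labeled_corpus",
    "simulate_submission",
    "random_lexicons",
    "random_article_spec",
    "generate_batch",
]

#: distractor vocabulary: plain lowercase words, no digits or hyphens, and
#: disjoint from all signal keywords and default species aliases.
WORDS: tuple[str, ...] = (
    "about", "above", "after", "again", "along", "among", "animal", "answer",
    "around", "assay", "basis", "because", "become", "before", "begin",
    "behavior", "below", "between", "beyond", "board", "bring", "broad",
    "carry", "cause", "certain", "change", "clear", "close", "common",
    "compare", "consider", "contain", "control", "could", "course", "create",
    "culture", "decrease", "define", "degree", "describe", "detail",
    "determine", "develop", "differ", "direct", "discuss", "divide", "double",
    "during", "early", "effect", "either", "embryo", "entire", "equal",
    "evidence", "examine", "example", "except", "expect", "explain", "extend",
    "factor", "figure", "final", "follow", "found", "further", "general",
    "govern", "great", "group", "growth", "happen", "having", "healthy",
    "include", "increase", "indicate", "involve", "larva", "large", "learn",
    "least", "leave", "level", "light", "limit", "little", "major", "marker",
    "material", "matter", "measure", "method", "might", "minute", "model",
    "moment", "naturally", "nearly", "never", "notice", "number", "observe",
    "obtain", "occur", "offer", "often", "order", "other", "panel", "paper",
    "pattern", "perform", "perhaps", "period", "place", "plate", "point",
    "possible", "prepare", "present", "previous", "probable", "problem",
    "process", "produce", "propose", "provide", "public", "question", "raise",
    "range", "rather", "reach", "reason", "recent", "record", "reduce",
    "region", "relate", "remain", "remember", "report", "require", "result",
    "return", "reveal", "sample", "second", "section", "separate", "serve",
    "several", "shape", "share", "short", "should", "simple", "since",
    "single", "small", "source", "special", "stage", "stand", "start",
    "state", "still", "strong", "study", "subject", "suggest", "support",
    "table", "therefore", "third", "though", "three", "through", "together",
    "toward", "travel", "under", "understand", "until", "usual", "value",
    "various", "water", "weight", "where", "whether", "which", "while",
    "whole", "within", "without", "worked", "would", "young",
)

#: keyword pools that mark a paper positive for each automatically
#: classified data type; hyphenated phrases survive the classifier tokenizer
#: as single tokens.
SIGNAL_KEYWORDS: dict[DataTypeLabel, tuple[str, ...]] = {
    DataTypeLabel.ALLELE_SEQUENCE_CHANGE: (
        "missense", "nonsense", "transversion", "base-substitution",
    ),
    DataTypeLabel.ANATOMIC_EXPRESSION: (
        "expression-pattern", "hypodermis", "pharynx", "reporter-fusion",
    ),
    DataTypeLabel.GENETIC_INTERACTIONS: (
        "suppressor", "enhancer", "epistasis", "synthetic-lethal",
    ),
    DataTypeLabel.PHYSICAL_INTERACTIONS: (
        "two-hybrid", "coimmunoprecipitation", "pulldown", "binding-assay",
    ),
    DataTypeLabel.REGULATORY_INTERACTIONS: (
        "upregulated", "downregulated", "transcriptional-target",
        "promoter-activity",
    ),
    DataTypeLabel.ALLELE_PHENOTYPE: (
        "uncoordinated", "sterile", "lethality", "mutant-phenotype",
    ),
    DataTypeLabel.RNAI_PHENOTYPE: (
        "rnai", "knockdown", "silencing", "feeding-rnai",
    ),
    DataTypeLabel.TRANSGENE_OVEREXPRESSION_PHENOTYPE: (
        "overexpression", "gain-of-function", "transgenic-array",
        "heat-shock-promoter",
    ),
}

#: binomials available to the species lexicon generator
SPECIES_POOL: tuple[tuple[str, str], ...] = (
    ("NCBITaxon:6239", "Caenorhabditis elegans"),
    ("NCBITaxon:6238", "Caenorhabditis briggsae"),
    ("NCBITaxon:7227", "Drosophila melanogaster"),
    ("NCBITaxon:7955", "Danio rerio"),
    ("NCBITaxon:9606", "Homo sapiens"),
    ("NCBITaxon:10090", "Mus musculus"),
    ("NCBITaxon:4932", "Saccharomyces cerevisiae"),
    ("NCBITaxon:562", "Escherichia coli"),
)


@dataclass(frozen=True)
class PlantedEntity:
    """One lexicon entry to plant: which form, how often, where."""

    entry: LexiconEntry
    title_count: int = 0
    body_count: int = 0
    form: str | None = None  # defaults to the entry's primary name

    def __post_init__(self) -> None:
        if self.title_count < 0 or self.body_count < 0:
            raise ValidationError("planted counts must be >= 0")
        if self.form is not None and self.form not in self.entry.surface_forms:
            raise ValidationError(
                f"{self.form!r} is not a surface form of "
                f"{self.entry.canonical_id!r}"
            )

    @property
    def planted_form(self) -> str:
        return self.form if self.form is not None else self.entry.primary_name


@dataclass(frozen=True)
class ArticleSpec:
    """Recipe for one synthetic article."""

    paper_id: str
    planted_entities: tuple[PlantedEntity, ...] = ()
    distractor_token_count: int = 80
    datatype_signals: Mapping[DataTypeLabel, tuple[tuple[str, ...], int]] = field(
        default_factory=dict
    )
    emails: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distractor_token_count < 0:
            raise ValidationError("distractor_token_count must be >= 0")
        for label, (keywords, count) in self.datatype_signals.items():
            if count < 0 or (count > 0 and not keywords):
                raise ValidationError(
                    f"bad signal spec for {label.value}: {keywords!r} x {count}"
                )


def _guard_forms(entry: LexiconEntry) -> set[str]:
    """Every string that could trigger a match for this entry."""
    forms = set(entry.surface_forms)
    if entry.entity_type is EntityType.GENE:
        forms.update(f.upper() for f in entry.surface_forms)
    if entry.entity_type is EntityType.SPECIES:
        for name in entry.surface_forms:
            parts = name.split()
            if len(parts) >= 2:
                forms.add(f"{parts[0][0]}. {' '.join(parts[1:])}")
        forms.update(DEFAULT_SPECIES_ALIASES.get(entry.primary_name, ()))
    return forms


def _check_substring_exclusion(spec: ArticleSpec) -> list[str]:
    """Validate the article recipe's no-accidental-overlap invariant;
    return the distractor pool it is safe to draw from."""
    guards: list[tuple[str, set[str]]] = [
        (p.entry.canonical_id, _guard_forms(p.entry))
        for p in spec.planted_entities
    ]
    signal_tokens = {
        kw
        for keywords, count in spec.datatype_signals.values()
        if count > 0
        for kw in keywords
    }
    for i, (id_a, forms_a) in enumerate(guards):
        for id_b, forms_b in guards[i + 1 :]:
            for f in forms_a:
                for g in forms_b:
                    if f in g or g in f:
                        raise ValidationError(
                            f"planted forms overlap: {f!r} ({id_a}) vs "
                            f"{g!r} ({id_b})"
                        )
        for f in forms_a:
            for kw in signal_tokens:
                if f in kw or kw in f:
                    raise ValidationError(
                        f"planted form {f!r} overlaps signal keyword {kw!r}"
                    )
            for email in spec.emails:
                if f in email:
                    raise ValidationError(
                        f"planted form {f!r} occurs inside email {email!r}"
                    )
    all_guard = {f for _, forms in guards for f in forms}
    pool = [
        w
        for w in WORDS
        if not any(f in w for f in all_guard)
        and w not in signal_tokens
    ]
    if not pool:
        raise ValidationError("no usable distractor words remain")
    return pool


def generate_article(
    spec: ArticleSpec, rng: random.Random | None = None
) -> tuple[Article, list[MentionCount], dict[DataTypeLabel, bool]]:
    """Build an article plus its ground-truth counts and data-type flags.

    Each planted form occurs exactly ``body_count`` boundary-valid times in
    the body and ``title_count`` times in the title.  Byte-identical output
    for a fixed seed.
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    pool = _check_substring_exclusion(spec)

    body_tokens = [rng.choice(pool) for _ in range(spec.distractor_token_count)]

    inserts: list[str] = []
    for planted in spec.planted_entities:
        inserts.extend([planted.planted_form] * planted.body_count)
    for label in sorted(spec.datatype_signals, key=lambda l: l.value):
        keywords, count = spec.datatype_signals[label]
        inserts.extend(rng.choice(keywords) for _ in range(count))
    rng.shuffle(inserts)
    for token in inserts:
        body_tokens.insert(rng.randrange(len(body_tokens) + 1), token)
    if spec.emails:
        body_tokens.append("correspondence:")
        body_tokens.extend(spec.emails)
    body = " ".join(body_tokens)

    title_tokens = [rng.choice(pool) for _ in range(5)]
    for planted in spec.planted_entities:
        for _ in range(planted.title_count):
            title_tokens.insert(
                rng.randrange(len(title_tokens) + 1), planted.planted_form
            )
    title = " ".join(title_tokens)

    article = Article(paper_id=spec.paper_id, title=title, abstract="", body=body)
    truth_counts = [
        MentionCount(
            canonical_id=p.entry.canonical_id,
            entity_type=p.entry.entity_type,
            title_count=p.title_count,
            text_count=p.body_count,
        )
        for p in spec.planted_entities
    ]
    truth_flags = {
        label: spec.datatype_signals.get(label, ((), 0))[1] > 0
        for label in DataTypeLabel
    }
    return article, truth_counts, truth_flags


def generate_labeled_corpus(
    n_pos: int,
    n_neg: int,
    label: DataTypeLabel,
    signal_insertion_prob: float = 1.0,
    seed: int = 0,
    *,
    n_signal_slots: int = 4,
    doc_tokens: int = 60,
) -> LabeledCorpus:
    """Balanced-by-construction corpus for one data type.

    Positives carry ``n_signal_slots`` independent chances (each with
    probability ``signal_insertion_prob``) of containing one of the label's
    signal keywords; negatives never contain any signal keyword.  All eight
    labels are recorded on every record (the other seven false).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one record per class")
    if not 0.0 <= signal_insertion_prob <= 1.0:
        raise ValidationError("signal_insertion_prob must be in [0, 1]")
    rng = random.Random(seed)
    keywords = SIGNAL_KEYWORDS[label]
    records = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        tokens = [rng.choice(WORDS) for _ in range(doc_tokens)]
        if positive:
            for _ in range(n_signal_slots):
                if rng.random() < signal_insertion_prob:
                    tokens.insert(
                        rng.randrange(len(tokens) + 1), rng.choice(keywords)
                    )
        article = Article(
            paper_id=f"{label.value}-{'pos' if positive else 'neg'}-{i:04d}",
            title=" ".join(tokens[:4]),
            abstract="",
            body=" ".join(tokens),
        )
        labels = {l: False for l in DataTypeLabel}
        labels[label] = positive
        records.append((article, labels))
    return LabeledCorpus(tuple(records))


# ---------------------------------------------------------------------------
# Submission simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubmissionErrorModel:
    """Independent author-error rates applied to a machine extraction."""

    removal_prob: float | Mapping[EntityType, float] = 0.0
    addition_prob: float | Mapping[EntityType, float] = 0.0
    flag_flip_prob: float = 0.0
    manual_entity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("removal_prob", "addition_prob"):
            value = getattr(self, name)
            probs = value.values() if isinstance(value, Mapping) else [value]
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValidationError(f"{name} must be within [0, 1]")
        if not 0.0 <= self.flag_flip_prob <= 1.0:
            raise ValidationError("flag_flip_prob must be within [0, 1]")
        if self.manual_entity_rate < 0:
            raise ValidationError("manual_entity_rate must be >= 0")

    def p_remove(self, entity_type: EntityType) -> float:
        if isinstance(self.removal_prob, Mapping):
            return self.removal_prob.get(entity_type, 0.0)
        return self.removal_prob

    def p_add(self, entity_type: EntityType) -> float:
        if isinstance(self.addition_prob, Mapping):
            return self.addition_prob.get(entity_type, 0.0)
        return self.addition_prob


@dataclass(frozen=True)
class EditRecord:
    """Ground-truth edits a simulated author made; for metric validation."""

    removed: Mapping[EntityType, frozenset[str]]
    added: Mapping[EntityType, frozenset[str]]
    flipped: frozenset[DataTypeLabel]


def _poisson(rng: random.Random, rate: float) -> int:
    # Knuth's method; rates here are small.
    if rate <= 0:
        return 0
    import math

    limit = math.exp(-rate)
    k, product = 0, rng.random()
    while product > limit:
        k += 1
        product *= rng.random()
    return k


_MANUAL_NAMERS = {
    "new_alleles": lambda rng: (
        "".join(rng.choice("abcdefghij") for _ in range(2))
        + str(rng.randrange(100, 1000))
    ),
    "new_strains": lambda rng: (
        "".join(rng.choice("KLMNOPQRST") for _ in range(2))
        + str(rng.randrange(1000, 10000))
    ),
    "new_transgenes": lambda rng: (
        "".join(rng.choice("abcdefghij") for _ in range(2))
        + rng.choice(("Is", "Ex"))
        + str(rng.randrange(100, 1000))
    ),
    "other_antibodies": lambda rng: (
        "anti-" + "".join(rng.choice("abcdefghij") for _ in range(3))
        + "-" + str(rng.randrange(1, 100))
    ),
}


def simulate_submission(
    extracted: ExtractionResult,
    flags: Mapping[DataTypeLabel, bool],
    model: SubmissionErrorModel,
    lexicons: Mapping[EntityType, Sequence[LexiconEntry]] | None = None,
    rng: random.Random | None = None,
    person_id: str = "WBPerson-synthetic",
) -> tuple[Submission, EditRecord]:
    """Author response to one machine extraction, with known edits.

    Each included entity is independently removed with the model's removal
    probability; each lexicon entry of the same type *not* extracted is
    added with the addition probability; each data-type flag is flipped
    with the flip probability.  Deterministic given the model seed (or an
    explicit rng).
    """
    rng = rng if rng is not None else random.Random(model.seed)
    lexicons = lexicons or {}

    final: dict[EntityType, frozenset[str]] = {}
    removed: dict[EntityType, frozenset[str]] = {}
    added: dict[EntityType, frozenset[str]] = {}
    for entity_type in EntityType:
        machine = sorted(extracted.included_ids(entity_type))
        p_rem = model.p_remove(entity_type)
        dropped = frozenset(c for c in machine if rng.random() < p_rem)
        p_add = model.p_add(entity_type)
        candidates = sorted(
            {e.canonical_id for e in lexicons.get(entity_type, ())}
            - set(machine)
        )
        gained = frozenset(c for c in candidates if rng.random() < p_add)
        final[entity_type] = frozenset(set(machine) - dropped) | gained
        removed[entity_type] = dropped
        added[entity_type] = gained

    flipped = frozenset(
        label
        for label in DataTypeLabel
        if rng.random() < model.flag_flip_prob
    )
    answers = {
        label: (bool(flags.get(label, False)) ^ (label in flipped))
        for label in DataTypeLabel
    }

    manual_entities = {
        category: tuple(
            _MANUAL_NAMERS[category](rng)
            for _ in range(_poisson(rng, model.manual_entity_rate))
        )
        for category in MANUAL_ENTITY_CATEGORIES
    }

    submission = Submission(
        paper_id=extracted.paper_id,
        person_id=person_id,
        status="complete",
        final_entities=final,
        flag_answers=answers,
        manual_datatype_answers={},
        manual_entities=manual_entities,
    )
    return submission, EditRecord(removed=removed, added=added, flipped=flipped)


# ---------------------------------------------------------------------------
# Random lexicons and mixed batches
# ---------------------------------------------------------------------------

_SEQ_LETTERS = "CFKMRTWY"


def _gene_name(rng: random.Random) -> str:
    stem = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(3))
    return f"{stem}-{rng.randrange(1, 80)}"


def _sequence_name(rng: random.Random) -> str:
    return (
        rng.choice(_SEQ_LETTERS)
        + f"{rng.randrange(10, 60)}"
        + rng.choice(_SEQ_LETTERS)
        + f"{rng.randrange(1, 10)}.{rng.randrange(1, 12)}"
    )


def _allele_name(rng: random.Random) -> str:
    prefix = "".join(
        rng.choice("abcdefghijklmnopqrstuvwxyz")
        for _ in range(rng.randrange(1, 4))
    )
    return f"{prefix}{rng.randrange(1, 4000)}"


def _strain_name(rng: random.Random) -> str:
    return (
        "".join(rng.choice("ABCDEFGHJKLMNPRSTUV") for _ in range(2))
        + str(rng.randrange(10, 6000))
    )


def _transgene_name(rng: random.Random) -> str:
    prefix = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(2))
    return f"{prefix}{rng.choice(('Is', 'Ex'))}{rng.randrange(1, 400)}"


def random_lexicons(
    rng: random.Random, n_per_type: int = 8, n_species: int = 4
) -> dict[EntityType, list[LexiconEntry]]:
    """Nomenclature-shaped random lexicons, free of substring collisions.

    Guarantees that across the whole lexicon set no surface form (nor any
    uppercase/abbreviated/alias variant) is a substring of another, so any
    subset can be planted into one article.
    """
    taken: set[str] = set()

    def admit(entry: LexiconEntry) -> bool:
        forms = _guard_forms(entry)
        for f in forms:
            for g in taken:
                if f in g or g in f:
                    return False
            if any(f in w for w in WORDS):
                return False
            for kws in SIGNAL_KEYWORDS.values():
                if any(f in kw or kw in f for kw in kws):
                    return False
        taken.update(forms)
        return True

    def draw(entity_type, id_prefix, n, make):
        entries = []
        counter = 1
        while len(entries) < n:
            entry = make(counter)
            if admit(entry):
                entries.append(entry)
            counter += 1
            if counter > 10000:
                raise ValidationError("cannot build collision-free lexicon")
        return entries

    lexicons: dict[EntityType, list[LexiconEntry]] = {}
    lexicons[EntityType.GENE] = draw(
        EntityType.GENE,
        "WBGene",
        n_per_type,
        lambda i: LexiconEntry(
            EntityType.GENE,
            f"WBGene{i:08d}",
            _gene_name(rng),
            (_sequence_name(rng),),
        ),
    )
    lexicons[EntityType.ALLELE] = draw(
        EntityType.ALLELE,
        "WBVar",
        n_per_type,
        lambda i: LexiconEntry(
            EntityType.ALLELE, f"WBVar{i:08d}", _allele_name(rng)
        ),
    )
    lexicons[EntityType.STRAIN] = draw(
        EntityType.STRAIN,
        "WBStrain",
        n_per_type,
        lambda i: LexiconEntry(
            EntityType.STRAIN, f"WBStrain{i:08d}", _strain_name(rng)
        ),
    )
    lexicons[EntityType.TRANSGENE] = draw(
        EntityType.TRANSGENE,
        "WBTransgene",
        n_per_type,
        lambda i: LexiconEntry(
            EntityType.TRANSGENE, f"WBTransgene{i:08d}", _transgene_name(rng)
        ),
    )
    species_entries = []
    for taxon_id, binomial in rng.sample(
        SPECIES_POOL, min(n_species, len(SPECIES_POOL))
    ):
        entry = LexiconEntry(EntityType.SPECIES, taxon_id, binomial)
        if admit(entry):
            species_entries.append(entry)
    lexicons[EntityType.SPECIES] = species_entries
    return lexicons


def random_article_spec(
    rng: random.Random,
    paper_id: str,
    lexicons: Mapping[EntityType, Sequence[LexiconEntry]],
    *,
    emails: tuple[str, ...] = (),
    p_plant: float = 0.4,
    p_title: float = 0.15,
    max_body_count: int = 4,
    p_signal: float = 0.3,
    distractor_tokens: tuple[int, int] = (60, 120),
) -> ArticleSpec:
    """A mixed-type article spec: random subset of entries at random counts."""
    planted = []
    for entity_type in EntityType:
        for entry in lexicons.get(entity_type, ()):
            if rng.random() >= p_plant:
                continue
            body_count = rng.randrange(0, max_body_count + 1)
            title_count = 1 if rng.random() < p_title else 0
            if body_count == 0 and title_count == 0:
                continue
            form = rng.choice(entry.surface_forms)
            planted.append(
                PlantedEntity(entry, title_count, body_count, form=form)
            )
    signals = {
        label: (SIGNAL_KEYWORDS[label], rng.randrange(2, 5))
        for label in DataTypeLabel
        if rng.random() < p_signal
    }
    return ArticleSpec(
        paper_id=paper_id,
        planted_entities=tuple(planted),
        distractor_token_count=rng.randrange(*distractor_tokens),
        datatype_signals=signals,
        emails=emails,
        seed=rng.randrange(2**31),
    )


def generate_batch(
    rng: random.Random,
    n_articles: int,
    lexicons: Mapping[EntityType, Sequence[LexiconEntry]],
    *,
    emails_pool: Sequence[str] = (),
    **spec_kwargs,
) -> tuple[
    list[Article],
    dict[str, list[MentionCount]],
    dict[str, dict[DataTypeLabel, bool]],
]:
    """Batch of mixed-type articles with per-paper ground truth."""
    articles: list[Article] = []
    truth_counts: dict[str, list[MentionCount]] = {}
    truth_flags: dict[str, dict[DataTypeLabel, bool]] = {}
    for i in range(n_articles):
        emails = (rng.choice(emails_pool),) if emails_pool else ()
        spec = random_article_spec(
            rng, f"WBPaper{i:08d}", lexicons, emails=emails, **spec_kwargs
        )
        article, counts, flags = generate_article(spec)
        articles.append(article)
        truth_counts[article.paper_id] = counts
        truth_flags[article.paper_id] = flags
    return articles, truth_counts, truth_flags
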