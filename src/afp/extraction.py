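"""Lexicon mention counting and per-type inclusion thresholds.

Entities can appear in a paper without being its experimental subject, so
each entity type has a minimum in-text mention count before it is reported:
genes and alleles require 2 mentions, strains and transgenes 1, species 10
(species names are routinely dropped into introductions for comparative
purposes, hence the much higher bar).  A single mention in the title
overrides the threshold for every type, since titles are a faithful
indication of what a paper is about.

Matching is word-boundary delimited: a hit may not be immediately preceded
or followed by a letter, digit or hyphen.  The hyphen is boundary-blocking
because nematode gene names contain internal hyphens ("lin-3" must not
match inside "pre-lin-3"; "lin-39" is already blocked by the digit rule).
Gene names are additionally matched in all-uppercase form, the community
convention for protein names (lin-3 -> LIN-3).  Species are matched by full
binomial ("Drosophila melanogaster"), abbreviated genus ("D. melanogaster")
and, for a configurable subset, common-name aliases ("zebrafish" for
Danio rerio), aliases case-insensitively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Article, EntityType, LexiconEntry, ValidationError

__all__ = [
    "MatchRuleSet",
    "MentionCount",
    "ExtractionResult",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_SPECIES_ALIASES",
    "count_occurrences",
    "count_species",
    "apply_inclusion_rule",
    "extract_entities",
    "species_aliases_for",
]

#: minimum number of in-text mentions before an entity is reported
DEFAULT_THRESHOLDS: dict[EntityType, int] = {
    EntityType.GENE: 2,
    EntityType.ALLELE: 2,
    EntityType.STRAIN: 1,
    EntityType.TRANSGENE: 1,
    EntityType.SPECIES: 10,
}

#: common-name aliases keyed by binomial; editable configuration, not ground truth
DEFAULT_SPECIES_ALIASES: dict[str, tuple[str, ...]] = {
    "Homo sapiens": ("human", "humans"),
    "Mus musculus": ("mouse", "mice"),
    "Rattus norvegicus": ("rat", "rats"),
    "Danio rerio": ("zebrafish",),
    "Drosophila melanogaster": ("fruitfly", "fruitflies"),
    "Saccharomyces cerevisiae": ("yeast",),
}

# characters that may not flank a match
_BOUNDARY = "A-Za-z0-9-"
_LEFT = f"(?<![{_BOUNDARY}])"
_RIGHT = f"(?![{_BOUNDARY}])"


@dataclass(frozen=True)
class MatchRuleSet:
    """Matching configuration: thresholds, protein-case rule, title override."""

    thresholds: Mapping[EntityType, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    uppercase_protein_rule: bool = True
    title_override: bool = True
    species_aliases: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, v in self.thresholds.items():
            if v < 1:
                raise ValidationError(f"threshold for {t} must be >= 1, got {v}")
        for cid, aliases in self.species_aliases.items():
            if any(not a for a in aliases):
                raise ValidationError(f"empty alias for {cid!r}")

    def threshold(self, entity_type: EntityType) -> int:
        try:
            return self.thresholds[entity_type]
        except KeyError:
            raise ValidationError(f"no threshold for {entity_type!r}") from None


@dataclass(frozen=True)
class MentionCount:
    canonical_id: str
    entity_type: EntityType
    title_count: int = 0
    text_count: int = 0


@dataclass(frozen=True)
class ExtractionResult:
    """Per-type entity lists for one paper.

    ``included`` holds only the entries passing the inclusion rule;
    ``all_counts`` every nonzero count (diagnostics).  Lists are sorted by
    canonical id.
    """

    paper_id: str
    included: Mapping[EntityType, tuple[MentionCount, ...]]
    all_counts: Mapping[EntityType, tuple[MentionCount, ...]]

    def included_ids(self, entity_type: EntityType) -> set[str]:
        return {m.canonical_id for m in self.included.get(entity_type, ())}

    @property
    def has_core_entities(self) -> bool:
        """True if any gene, allele, strain or transgene passed inclusion."""
        core = (
            EntityType.GENE,
            EntityType.ALLELE,
            EntityType.STRAIN,
            EntityType.TRANSGENE,
        )
        return any(self.included.get(t) for t in core)


def _compile(forms: Sequence[str], case_insensitive: bool = False) -> re.Pattern[str]:
    # Longest form first: Python's alternation takes the first branch that
    # matches at a position, which yields longest-match tie-breaking; the
    # scanner then resumes after the match end, so counts never overlap.
    ordered = sorted(set(forms), key=lambda f: (-len(f), f))
    alternation = "|".join(re.escape(f) for f in ordered)
    flags = re.IGNORECASE if case_insensitive else 0
    return re.compile(f"{_LEFT}(?:{alternation}){_RIGHT}", flags)


def count_occurrences(
    text: str, surface_forms: Sequence[str], uppercase_rule: bool = False
) -> int:
    """Number of boundary-valid, non-overlapping occurrences of any form.

    With ``uppercase_rule`` the all-uppercase variant of each form also
    counts (protein-name convention).  Overlapping candidates at the same
    start position count once, longest form wins.
    """
    if not surface_forms:
        raise ValidationError("surface_forms must be non-empty")
    if not text:
        return 0
    forms = list(surface_forms)
    if uppercase_rule:
        forms.extend(f.upper() for f in surface_forms)
    return sum(1 for _ in _compile(forms).finditer(text))


def _binomial_forms(primary_name: str) -> tuple[str, str]:
    parts = primary_name.split()
    if len(parts) < 2 or not re.fullmatch(r"[A-Z][A-Za-z]*", parts[0]):
        raise ValidationError(
            f"species primary name {primary_name!r} is not a binomial"
        )
    abbreviated = f"{parts[0][0]}. {' '.join(parts[1:])}"
    return primary_name, abbreviated


def count_species(
    text: str, entry: LexiconEntry, aliases: Sequence[str] = ()
) -> int:
    """Mentions of a species: full or abbreviated binomial, or alias.

    Binomials are matched case-sensitively (a lowercase "d. melanogaster"
    is a conversion artifact, not a mention); aliases case-insensitively.
    Synonym binomials on the entry are matched both ways too.
    """
    if not text:
        _binomial_forms(entry.primary_name)  # still validate
        return 0
    binomial_forms: list[str] = []
    for name in entry.surface_forms:
        binomial_forms.extend(_binomial_forms(name))
    # A single left-to-right scan over the union keeps the non-overlap rule
    # consistent across the case-sensitive and case-insensitive pattern.
    count = 0
    pat_exact = _compile(binomial_forms)
    pat_alias = _compile(aliases, case_insensitive=True) if aliases else None
    pos = 0
    while pos <= len(text):
        m_exact = pat_exact.search(text, pos)
        m_alias = pat_alias.search(text, pos) if pat_alias else None
        if m_exact is None and m_alias is None:
            break
        candidates = [m for m in (m_exact, m_alias) if m is not None]
        best = min(candidates, key=lambda m: (m.start(), -len(m.group(0))))
        count += 1
        pos = max(best.end(), pos + 1)
    return count


def apply_inclusion_rule(m: MentionCount, rules: MatchRuleSet) -> bool:
    """In-text count at/above threshold, or a single title mention."""
    if m.text_count >= rules.threshold(m.entity_type):
        return True
    return rules.title_override and m.title_count >= 1


def species_aliases_for(entry: LexiconEntry, rules: MatchRuleSet) -> tuple[str, ...]:
    """Aliases for a species entry: rule-set override, else default table."""
    if entry.canonical_id in rules.species_aliases:
        return tuple(rules.species_aliases[entry.canonical_id])
    return DEFAULT_SPECIES_ALIASES.get(entry.primary_name, ())


def _count_for_entry(
    text: str, entry: LexiconEntry, rules: MatchRuleSet
) -> int:
    if entry.entity_type is EntityType.SPECIES:
        return count_species(text, entry, species_aliases_for(entry, rules))
    uppercase = rules.uppercase_protein_rule and entry.entity_type is EntityType.GENE
    return count_occurrences(text, entry.surface_forms, uppercase)


def extract_entities(
    article: Article,
    lexicons: Mapping[EntityType, Iterable[LexiconEntry]],
    rules: MatchRuleSet | None = None,
) -> ExtractionResult:
    """Count every lexicon entry in title and text and apply inclusion rules."""
    rules = rules or MatchRuleSet()
    text = article.searchable_text
    included: dict[EntityType, tuple[MentionCount, ...]] = {}
    all_counts: dict[EntityType, tuple[MentionCount, ...]] = {}
    for entity_type, entries in lexicons.items():
        nonzero: list[MentionCount] = []
        passing: list[MentionCount] = []
        for entry in entries:
            title_count = (
                _count_for_entry(article.title, entry, rules)
                if article.title
                else 0
            )
            text_count = _count_for_entry(text, entry, rules)
            if title_count == 0 and text_count == 0:
                continue
            m = MentionCount(entry.canonical_id, entity_type, title_count, text_count)
            nonzero.append(m)
            if apply_inclusion_rule(m, rules):
                passing.append(m)
        key = lambda m: m.canonical_id
        included[entity_type] = tuple(sorted(passing, key=key))
        all_counts[entity_type] = tuple(sorted(nonzero, key=key))
    return ExtractionResult(article.paper_id, included, all_counts)
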