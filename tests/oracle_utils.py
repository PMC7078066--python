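"""Brute-force mention-counting oracle, independent of the regex engine.

Enumerates every occurrence of every surface form by direct string
scanning, applies the boundary test character by character, then resolves
overlaps greedily left to right with longest-wins at equal starts.  Used
to cross-check the production matcher, never to implement it.
"""

from afp.corpus import Article, EntityType, LexiconEntry
from afp.extraction import MatchRuleSet, species_aliases_for

_BOUNDARY_CHARS = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-"
)


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and text[start - 1] in _BOUNDARY_CHARS:
        return False
    if end < len(text) and text[end] in _BOUNDARY_CHARS:
        return False
    return True


def _find_all(haystack: str, needle: str) -> list[int]:
    starts, i = [], haystack.find(needle)
    while i != -1:
        starts.append(i)
        i = haystack.find(needle, i + 1)
    return starts


def oracle_count(text: str, exact_forms, ci_forms=()) -> int:
    """Non-overlapping boundary-valid occurrences of any form."""
    occurrences: list[tuple[int, int]] = []
    for form in set(exact_forms):
        for start in _find_all(text, form):
            if _boundary_ok(text, start, start + len(form)):
                occurrences.append((start, len(form)))
    lowered = text.lower()
    for form in set(f.lower() for f in ci_forms):
        for start in _find_all(lowered, form):
            if _boundary_ok(text, start, start + len(form)):
                occurrences.append((start, len(form)))
    count, pos = 0, 0
    for start, length in sorted(set(occurrences), key=lambda o: (o[0], -o[1])):
        if start >= pos:
            count += 1
            pos = start + length
    return count


def oracle_entry_count(text: str, entry: LexiconEntry, rules: MatchRuleSet) -> int:
    if entry.entity_type is EntityType.SPECIES:
        exact = []
        for name in entry.surface_forms:
            parts = name.split()
            exact.append(name)
            exact.append(f"{parts[0][0]}. {' '.join(parts[1:])}")
        return oracle_count(text, exact, species_aliases_for(entry, rules))
    forms = list(entry.surface_forms)
    if rules.uppercase_protein_rule and entry.entity_type is EntityType.GENE:
        forms += [f.upper() for f in entry.surface_forms]
    return oracle_count(text, forms)


def oracle_extract_sets(
    article: Article, lexicons, rules: MatchRuleSet
) -> dict[EntityType, set[str]]:
    """Included-entity id sets per type, by exhaustive scan."""
    included: dict[EntityType, set[str]] = {}
    for entity_type, entries in lexicons.items():
        ids = set()
        for entry in entries:
            title = oracle_entry_count(article.title, entry, rules)
            text = oracle_entry_count(article.searchable_text, entry, rules)
            threshold = rules.thresholds[entity_type]
            if text >= threshold or (rules.title_override and title >= 1):
                ids.add(entry.canonical_id)
        included[entity_type] = ids
    return included
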