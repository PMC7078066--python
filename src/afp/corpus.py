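"""Data model and I/O for articles, entity lexicons and the person registry.

Articles are plain-text records (title / abstract / body).  The title is kept
separate from the rest of the text because a single title mention of an
entity is treated as a true positive regardless of the in-text thresholds;
the threshold rules themselves are applied to ``searchable_text`` (abstract
concatenated with body).

Lexicons are controlled vocabularies: one canonical database identifier per
entry plus its surface forms (a primary name and any synonyms, e.g. a gene's
public name and its sequence name).  The person registry maps author email
addresses to curated person identifiers.

All files are UTF-8; strings are normalized to Unicode NFC on load so that
typographic variants produced by text conversion do not break name matching.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "EntityType",
    "LexiconEntry",
    "Article",
    "PersonRegistry",
    "ValidationError",
    "SEPARATOR",
    "load_lexicon",
    "save_lexicon",
    "load_articles",
    "save_articles",
    "load_person_registry",
    "save_person_registry",
]

#: separator between abstract and body in ``Article.searchable_text``
SEPARATOR = "\n"


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


class EntityType(str, Enum):
    """The five entity classes extracted from papers."""

    GENE = "gene"
    ALLELE = "allele"
    STRAIN = "strain"
    TRANSGENE = "transgene"
    SPECIES = "species"


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class LexiconEntry:
    """One controlled-vocabulary term of a given entity type.

    ``canonical_id`` is the stable database identifier (e.g. a WBGene id);
    ``primary_name`` and ``synonyms`` together form the surface forms that
    are searched for in text.
    """

    entity_type: EntityType
    canonical_id: str
    primary_name: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise ValidationError("canonical_id must be non-empty")
        if not self.primary_name:
            raise ValidationError(
                f"empty primary_name for {self.canonical_id!r}"
            )
        if any(not s for s in self.synonyms):
            raise ValidationError(
                f"empty synonym for {self.canonical_id!r}"
            )
        if self.primary_name in self.synonyms:
            raise ValidationError(
                f"primary name {self.primary_name!r} repeated in synonyms"
            )

    @property
    def surface_forms(self) -> tuple[str, ...]:
        """Primary name followed by synonyms; never empty."""
        return (self.primary_name, *self.synonyms)


@dataclass(frozen=True)
class Article:
    """A paper as structured plain text.

    ``searchable_text`` (abstract + separator + body) is the document the
    in-text mention thresholds apply to; the title is searched separately.
    """

    paper_id: str
    title: str = ""
    abstract: str = ""
    body: str = ""

    def __post_init__(self) -> None:
        if not self.paper_id:
            raise ValidationError("paper_id must be non-empty")

    @property
    def searchable_text(self) -> str:
        return self.abstract + SEPARATOR + self.body

    @property
    def has_text(self) -> bool:
        """False when abstract and body contain no non-whitespace text."""
        return bool(self.abstract.strip() or self.body.strip())


class PersonRegistry:
    """Case-insensitive mapping from email address to person identifier."""

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._emails: dict[str, str] = {}
        for email, person_id in (mapping or {}).items():
            self.add(email, person_id)

    def add(self, email: str, person_id: str) -> None:
        key = _nfc(email).lower()
        if key in self._emails and self._emails[key] != person_id:
            raise ValidationError(
                f"email {key!r} mapped to both {self._emails[key]!r} "
                f"and {person_id!r}"
            )
        self._emails[key] = person_id

    def lookup(self, email: str) -> str | None:
        """Person id for ``email`` (case-insensitive), or None."""
        return self._emails.get(_nfc(email).lower())

    def __len__(self) -> int:
        return len(self._emails)

    def __contains__(self, email: str) -> bool:
        return self.lookup(email) is not None

    def items(self) -> Iterable[tuple[str, str]]:
        return self._emails.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PersonRegistry):
            return NotImplemented
        return self._emails == other._emails


# ---------------------------------------------------------------------------
# Lexicon TSV: canonical_id <TAB> primary_name <TAB> pipe-separated synonyms
# (third column optional).
# ---------------------------------------------------------------------------

def load_lexicon(path: str | Path, entity_type: EntityType) -> list[LexiconEntry]:
    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValidationError(
                    f"{path}: row {lineno}: expected at least 2 columns"
                )
            canonical_id = _nfc(row[0].strip())
            primary = _nfc(row[1].strip())
            if not primary:
                raise ValidationError(
                    f"{path}: row {lineno}: empty primary_name"
                )
            if canonical_id in seen:
                raise ValidationError(
                    f"{path}: duplicate canonical_id {canonical_id!r}"
                )
            seen.add(canonical_id)
            synonyms: tuple[str, ...] = ()
            if len(row) >= 3 and row[2].strip():
                synonyms = tuple(
                    _nfc(s.strip()) for s in row[2].split("|") if s.strip()
                )
            entries.append(
                LexiconEntry(entity_type, canonical_id, primary, synonyms)
            )
    return entries


def save_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in entries:
            writer.writerow([e.canonical_id, e.primary_name, "|".join(e.synonyms)])


# ---------------------------------------------------------------------------
# Articles: JSON-lines with keys paper_id, title, abstract, body.
# ---------------------------------------------------------------------------

def load_articles(path: str | Path) -> list[Article]:
    articles: list[Article] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: malformed JSON ({exc.msg})"
                ) from exc
            if not isinstance(record, dict) or not record.get("paper_id"):
                raise ValidationError(
                    f"{path}: line {lineno}: missing paper_id"
                )
            paper_id = _nfc(str(record["paper_id"]))
            if paper_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate paper_id {paper_id!r}"
                )
            seen.add(paper_id)
            articles.append(
                Article(
                    paper_id=paper_id,
                    title=_nfc(str(record.get("title", ""))),
                    abstract=_nfc(str(record.get("abstract", ""))),
                    body=_nfc(str(record.get("body", ""))),
                )
            )
    return articles


def save_articles(articles: Iterable[Article], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {
                        "paper_id": a.paper_id,
                        "title": a.title,
                        "abstract": a.abstract,
                        "body": a.body,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Person registry TSV: email <TAB> person_id.
# ---------------------------------------------------------------------------

def load_person_registry(path: str | Path) -> PersonRegistry:
    registry = PersonRegistry()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValidationError(
                    f"{path}: row {lineno}: expected 2 columns"
                )
            registry.add(row[0].strip(), _nfc(row[1].strip()))
    return registry


def save_person_registry(registry: PersonRegistry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for email, person_id in sorted(registry.items()):
            writer.writerow([email, person_id])
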