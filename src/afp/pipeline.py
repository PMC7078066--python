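"""Batch triage orchestration.

A weekly run consumes up to 50 queued articles (lexicographic paper-id
order), drops papers whose text conversion produced nothing, extracts and
classifies the rest, and discards papers with no genes, alleles, strains or
transgenes — those are not relevant for author-validated curation.  For
each surviving paper the corresponding author is resolved as the first
email address in the text that matches the person registry, and a
notification record carrying a randomized access token is emitted.  Authors
who do not finalize their submission are reminded after 30 and 60 days, at
most twice.

Email delivery itself is an integration concern: the pipeline emits
notification and reminder records, never SMTP traffic.  Processed paper ids
and notification records persist in a JSON state store so that re-running a
batch never re-processes or re-notifies a paper.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classify import ClassifierModel, DataTypeFlags, DataTypeLabel, classify_all
from .corpus import Article, EntityType, LexiconEntry, PersonRegistry, ValidationError
from .extraction import ExtractionResult, MatchRuleSet, MentionCount, extract_entities

__all__ = [
    "TriageStatus",
    "TriageDecision",
    "NotificationRecord",
    "RunReport",
    "PipelineState",
    "EMAIL_RE",
    "find_corresponding_author",
    "generate_token",
    "run_batch",
    "due_reminders",
]

# RFC-lite address pattern; full RFC 5322 parsing is out of scope.
EMAIL_RE = re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}")

#: days after notification at which reminders 1 and 2 become due
REMINDER_DAYS = (30, 60)
MAX_REMINDERS = 2


class TriageStatus(str, Enum):
    PROCESSED = "processed"
    DISCARDED_EMPTY_TEXT = "discarded_empty_text"
    DISCARDED_NO_ENTITIES = "discarded_no_entities"


class SubmissionStatus(str, Enum):
    NONE = "none"
    PARTIAL = "partial"
    COMPLETE = "complete"


@dataclass(frozen=True)
class TriageDecision:
    paper_id: str
    status: TriageStatus


@dataclass(frozen=True)
class NotificationRecord:
    """State of one author notification (token link, reminders, submission)."""

    paper_id: str
    email: str
    person_id: str
    token: str
    sent_at: date
    reminders_sent: int = 0
    submission_status: SubmissionStatus = SubmissionStatus.NONE

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[0-9a-f]{32}", self.token):
            raise ValidationError(f"malformed token {self.token!r}")
        if not 0 <= self.reminders_sent <= MAX_REMINDERS:
            raise ValidationError(
                f"reminders_sent must be 0..{MAX_REMINDERS}"
            )


@dataclass(frozen=True)
class RunReport:
    """Everything one batch run produced."""

    run_date: date
    decisions: tuple[TriageDecision, ...]
    extractions: tuple[ExtractionResult, ...]
    flags: tuple[DataTypeFlags, ...]
    notifications: tuple[NotificationRecord, ...]
    author_unresolved: tuple[str, ...] = ()
    queued_remaining: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n_processed = sum(
            1 for d in self.decisions if d.status is TriageStatus.PROCESSED
        )
        if not (n_processed == len(self.extractions) == len(self.flags)):
            raise ValidationError(
                "processed decisions, extractions and flags must align"
            )


@dataclass
class PipelineState:
    """Persistent store: processed paper ids and notification records."""

    processed_ids: set[str] = field(default_factory=set)
    notifications: list[NotificationRecord] = field(default_factory=list)

    @property
    def tokens(self) -> set[str]:
        return {n.token for n in self.notifications}

    def save(self, path: str | Path) -> None:
        payload = {
            "processed_ids": sorted(self.processed_ids),
            "notifications": [
                {
                    "paper_id": n.paper_id,
                    "email": n.email,
                    "person_id": n.person_id,
                    "token": n.token,
                    "sent_at": n.sent_at.isoformat(),
                    "reminders_sent": n.reminders_sent,
                    "submission_status": n.submission_status.value,
                }
                for n in self.notifications
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineState":
        payload = json.loads(Path(path).read_text("utf-8"))
        return cls(
            processed_ids=set(payload.get("processed_ids", ())),
            notifications=[
                NotificationRecord(
                    paper_id=r["paper_id"],
                    email=r["email"],
                    person_id=r["person_id"],
                    token=r["token"],
                    sent_at=date.fromisoformat(r["sent_at"]),
                    reminders_sent=int(r.get("reminders_sent", 0)),
                    submission_status=SubmissionStatus(
                        r.get("submission_status", "none")
                    ),
                )
                for r in payload.get("notifications", ())
            ],
        )


def find_corresponding_author(
    text: str, registry: PersonRegistry
) -> tuple[str, str] | None:
    """First registry-matched email address by text position, or None.

    Addresses earlier in the text that are unknown to the registry are
    skipped; the corresponding author is the first *matched* one.
    """
    for m in EMAIL_RE.finditer(text):
        person_id = registry.lookup(m.group(0))
        if person_id is not None:
            return m.group(0).lower(), person_id
    return None


def generate_token(
    rng: random.Random, existing: Iterable[str] = ()
) -> str:
    """32 lowercase hex characters, collision-checked against ``existing``."""
    taken = set(existing)
    while True:
        token = f"{rng.getrandbits(128):032x}"
        if token not in taken:
            return token


def run_batch(
    articles: Sequence[Article],
    lexicons: Mapping[EntityType, Sequence[LexiconEntry]],
    models: Mapping[DataTypeLabel, ClassifierModel],
    rules: MatchRuleSet | None = None,
    registry: PersonRegistry | None = None,
    *,
    batch_cap: int = 50,
    rng: random.Random | None = None,
    state: PipelineState | None = None,
    run_date: date | None = None,
) -> RunReport:
    """Run one triage batch over the queued articles.

    The queue is the articles sorted by paper id, minus ids already in the
    state store.  At most ``batch_cap`` articles are consumed (discarded
    papers count as consumed); the remainder stay queued.  ``state`` is
    updated in place with processed ids and new notifications.
    """
    rules = rules or MatchRuleSet()
    registry = registry or PersonRegistry()
    rng = rng or random.Random(0)
    state = state if state is not None else PipelineState()
    run_date = run_date or date.today()

    queue = sorted(
        (a for a in articles if a.paper_id not in state.processed_ids),
        key=lambda a: a.paper_id,
    )
    batch, remaining = queue[:batch_cap], queue[batch_cap:]

    decisions: list[TriageDecision] = []
    extractions: list[ExtractionResult] = []
    flags: list[DataTypeFlags] = []
    notifications: list[NotificationRecord] = []
    unresolved: list[str] = []

    for article in batch:
        if not article.has_text:
            decisions.append(
                TriageDecision(article.paper_id, TriageStatus.DISCARDED_EMPTY_TEXT)
            )
            state.processed_ids.add(article.paper_id)
            continue
        extraction = extract_entities(article, lexicons, rules)
        if not extraction.has_core_entities:
            decisions.append(
                TriageDecision(article.paper_id, TriageStatus.DISCARDED_NO_ENTITIES)
            )
            state.processed_ids.add(article.paper_id)
            continue
        decisions.append(TriageDecision(article.paper_id, TriageStatus.PROCESSED))
        extractions.append(extraction)
        flags.append(classify_all(article, models))
        state.processed_ids.add(article.paper_id)

        author = find_corresponding_author(
            f"{article.title}\n{article.searchable_text}", registry
        )
        if author is None:
            unresolved.append(article.paper_id)
            continue
        email, person_id = author
        token = generate_token(rng, state.tokens)
        record = NotificationRecord(
            paper_id=article.paper_id,
            email=email,
            person_id=person_id,
            token=token,
            sent_at=run_date,
        )
        notifications.append(record)
        state.notifications.append(record)

    return RunReport(
        run_date=run_date,
        decisions=tuple(decisions),
        extractions=tuple(extractions),
        flags=tuple(flags),
        notifications=tuple(notifications),
        author_unresolved=tuple(unresolved),
        queued_remaining=tuple(a.paper_id for a in remaining),
    )


def due_reminders(
    records: Sequence[NotificationRecord], now: date
) -> list[tuple[str, int]]:
    """(paper_id, reminder_number) pairs due at ``now``.

    Reminder k (1-based) is due when the submission is not complete,
    exactly k-1 reminders were sent, and at least 30*k days have elapsed
    since notification.  Nothing is ever due after two reminders.
    """
    due: list[tuple[str, int]] = []
    for rec in records:
        if rec.submission_status is SubmissionStatus.COMPLETE:
            continue
        if rec.reminders_sent >= MAX_REMINDERS:
            continue
        next_number = rec.reminders_sent + 1
        if (now - rec.sent_at).days >= REMINDER_DAYS[next_number - 1]:
            due.append((rec.paper_id, next_number))
    return due


def mark_reminder_sent(
    state: PipelineState, paper_id: str, reminder_number: int
) -> None:
    """Record that a due reminder was emitted for a paper."""
    for i, rec in enumerate(state.notifications):
        if rec.paper_id == paper_id:
            if rec.reminders_sent != reminder_number - 1:
                raise ValidationError(
                    f"{paper_id}: reminder {reminder_number} out of order "
                    f"(already sent {rec.reminders_sent})"
                )
            state.notifications[i] = replace(
                rec, reminders_sent=reminder_number
            )
            return
    raise ValidationError(f"no notification record for {paper_id!r}")
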