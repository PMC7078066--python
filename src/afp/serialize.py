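"""JSON dict forms for extraction results, flags and run reports.

These are the on-disk shapes the command-line interface reads and writes;
they are stable, sorted-key and text-only so that report files are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from datetime import date
from typing import Mapping

from .classify import DataTypeFlags, DataTypeLabel
from .corpus import EntityType
from .extraction import ExtractionResult, MentionCount
from .pipeline import (
    NotificationRecord,
    RunReport,
    SubmissionStatus,
    TriageDecision,
    TriageStatus,
)

__all__ = [
    "extraction_to_dict",
    "extraction_from_dict",
    "flags_to_dict",
    "flags_from_dict",
    "report_to_dict",
    "report_from_dict",
]


def _mentions_to_list(mentions) -> list[dict]:
    return [
        {
            "canonical_id": m.canonical_id,
            "title_count": m.title_count,
            "text_count": m.text_count,
        }
        for m in mentions
    ]


def extraction_to_dict(res: ExtractionResult) -> dict:
    return {
        "paper_id": res.paper_id,
        "included": {
            t.value: _mentions_to_list(res.included.get(t, ()))
            for t in EntityType
        },
        "all_counts": {
            t.value: _mentions_to_list(res.all_counts.get(t, ()))
            for t in EntityType
        },
    }


def _mentions_from_list(items, entity_type: EntityType) -> tuple[MentionCount, ...]:
    return tuple(
        MentionCount(
            canonical_id=m["canonical_id"],
            entity_type=entity_type,
            title_count=int(m["title_count"]),
            text_count=int(m["text_count"]),
        )
        for m in items
    )


def extraction_from_dict(payload: Mapping) -> ExtractionResult:
    return ExtractionResult(
        paper_id=payload["paper_id"],
        included={
            EntityType(t): _mentions_from_list(items, EntityType(t))
            for t, items in payload.get("included", {}).items()
        },
        all_counts={
            EntityType(t): _mentions_from_list(items, EntityType(t))
            for t, items in payload.get("all_counts", {}).items()
        },
    )


def flags_to_dict(flags: DataTypeFlags) -> dict:
    return {
        label.value: {"flag": fm[0], "margin": fm[1]}
        for label, fm in flags.flags.items()
    }


def flags_from_dict(payload: Mapping) -> DataTypeFlags:
    return DataTypeFlags(
        {
            DataTypeLabel(l): (bool(v["flag"]), float(v["margin"]))
            for l, v in payload.items()
        }
    )


def report_to_dict(report: RunReport) -> dict:
    return {
        "run_date": report.run_date.isoformat(),
        "decisions": [
            {"paper_id": d.paper_id, "status": d.status.value}
            for d in report.decisions
        ],
        "extractions": [extraction_to_dict(e) for e in report.extractions],
        "flags": [flags_to_dict(f) for f in report.flags],
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
            for n in report.notifications
        ],
        "author_unresolved": list(report.author_unresolved),
        "queued_remaining": list(report.queued_remaining),
    }


def report_from_dict(payload: Mapping) -> RunReport:
    return RunReport(
        run_date=date.fromisoformat(payload["run_date"]),
        decisions=tuple(
            TriageDecision(d["paper_id"], TriageStatus(d["status"]))
            for d in payload.get("decisions", ())
        ),
        extractions=tuple(
            extraction_from_dict(e) for e in payload.get("extractions", ())
        ),
        flags=tuple(flags_from_dict(f) for f in payload.get("flags", ())),
        notifications=tuple(
            NotificationRecord(
                paper_id=n["paper_id"],
                email=n["email"],
                person_id=n["person_id"],
                token=n["token"],
                sent_at=date.fromisoformat(n["sent_at"]),
                reminders_sent=int(n.get("reminders_sent", 0)),
                submission_status=SubmissionStatus(
                    n.get("submission_status", "none")
                ),
            )
            for n in payload.get("notifications", ())
        ),
        author_unresolved=tuple(payload.get("author_unresolved", ())),
        queued_remaining=tuple(payload.get("queued_remaining", ())),
    )
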