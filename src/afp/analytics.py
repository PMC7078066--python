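"""Author submissions and agreement statistics.

Authors validate machine-extracted entity lists and data-type flags in a
web form; comparing what the machine proposed with what the author
finalized quantifies extraction quality.  Per entity type we report the
entities added and removed per submission and the Jaccard coefficient
|A∩B|/|A∪B| between the extracted and final sets.  Flag agreement is
summarized with confusion-matrix accuracy (correct predictions over all
submissions), precision and recall.  Dashboard statistics mirror what a
curation team monitors: papers processed and discarded, complete and
partial submissions, the response rate among emailed papers, entity-count
distributions and the mean number of genes in non-empty submissions.
"""

from __future__ import annotations

import json
import statistics
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classify import DataTypeLabel
from .corpus import EntityType, ValidationError
from .extraction import ExtractionResult
from .pipeline import RunReport, TriageStatus

__all__ = [
    "MANUAL_DATATYPES",
    "MANUAL_ENTITY_CATEGORIES",
    "Submission",
    "TypeDiff",
    "DiffReport",
    "ConfusionCounts",
    "Agreement",
    "DashboardStats",
    "jaccard",
    "diff_submission",
    "confusion",
    "agreement",
    "dashboard_stats",
    "mean_added_removed",
    "load_submissions",
    "save_submissions",
]

#: data types authors classify manually (no automatic classifier exists)
MANUAL_DATATYPES = (
    "gene_model_update",
    "new_antibody",
    "site_of_action",
    "time_of_action",
    "rnaseq_data",
    "chemical_phenotype",
    "environmental_phenotype",
    "enzymatic_activity",
    "human_disease_model",
)

#: entity categories authors may add free-form (not yet in any lexicon)
MANUAL_ENTITY_CATEGORIES = (
    "new_alleles",
    "new_strains",
    "new_transgenes",
    "other_antibodies",
)


@dataclass(frozen=True)
class Submission:
    """An author's validated (or partially validated) response for one paper.

    Entity ids are plain strings, deliberately not validated against the
    lexicons: authors may add novel names the database has never seen.
    """

    paper_id: str
    person_id: str
    status: str  # "partial" | "complete"
    final_entities: Mapping[EntityType, frozenset[str]]
    flag_answers: Mapping[DataTypeLabel, bool]
    manual_datatype_answers: Mapping[str, bool] = field(default_factory=dict)
    manual_entities: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    comments: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("partial", "complete"):
            raise ValidationError(f"bad submission status {self.status!r}")
        unknown = set(self.manual_datatype_answers) - set(MANUAL_DATATYPES)
        if unknown:
            raise ValidationError(f"unknown manual data types: {sorted(unknown)}")
        unknown = set(self.manual_entities) - set(MANUAL_ENTITY_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown manual entity categories: {sorted(unknown)}")
        if self.status == "complete":
            missing = [l for l in DataTypeLabel if l not in self.flag_answers]
            if missing:
                raise ValidationError(
                    f"complete submission {self.paper_id!r} lacks flag answers: "
                    f"{[m.value for m in missing]}"
                )

    def gene_count(self) -> int:
        return len(self.final_entities.get(EntityType.GENE, frozenset()))


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a∩b| / |a∪b|; 0 for disjoint sets, 1 for equal sets.

    Two empty sets agree perfectly that nothing is present -> 1.0.
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass(frozen=True)
class TypeDiff:
    added: frozenset[str]  # submitted but not extracted
    removed: frozenset[str]  # extracted but not kept by the author
    jaccard: float

    def __post_init__(self) -> None:
        if self.added & self.removed:
            raise ValidationError("added and removed sets must be disjoint")


@dataclass(frozen=True)
class DiffReport:
    paper_id: str
    per_type: Mapping[EntityType, TypeDiff]


def diff_submission(extracted: ExtractionResult, submitted: Submission) -> DiffReport:
    """Per-type added/removed sets and Jaccard between machine and author."""
    if extracted.paper_id != submitted.paper_id:
        raise ValidationError(
            f"paper id mismatch: {extracted.paper_id!r} vs {submitted.paper_id!r}"
        )
    per_type: dict[EntityType, TypeDiff] = {}
    for entity_type in EntityType:
        machine = extracted.included_ids(entity_type)
        final = set(submitted.final_entities.get(entity_type, frozenset()))
        per_type[entity_type] = TypeDiff(
            added=frozenset(final - machine),
            removed=frozenset(machine - final),
            jaccard=jaccard(machine, final),
        )
    return DiffReport(extracted.paper_id, per_type)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    predicted: Sequence[bool], reference: Sequence[bool]
) -> ConfusionCounts:
    """Confusion counts over paired boolean vectors."""
    if len(predicted) != len(reference):
        raise ValidationError(
            f"length mismatch: {len(predicted)} vs {len(reference)}"
        )
    if not predicted:
        raise ValidationError("empty vectors")
    tp = fp = fn = tn = 0
    for p, r in zip(predicted, reference):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass(frozen=True)
class Agreement:
    """Accuracy / precision / recall; None marks an undefined ratio.

    Undefined values (zero denominator) are explicit rather than coerced to
    zero, and are excluded from any averaging done by callers.
    """

    accuracy: float
    precision: float | None
    recall: float | None

    def __iter__(self):
        return iter((self.accuracy, self.precision, self.recall))


def agreement(c: ConfusionCounts) -> Agreement:
    if c.n == 0:
        raise ValidationError("cannot compute agreement on zero counts")
    accuracy = (c.tp + c.tn) / c.n
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    return Agreement(accuracy, precision, recall)


def mean_added_removed(
    diffs: Sequence[DiffReport], entity_type: EntityType
) -> tuple[float, float, float]:
    """(mean added, mean removed, mean Jaccard) across submissions."""
    if not diffs:
        raise ValidationError("no diffs to average")
    added = [len(d.per_type[entity_type].added) for d in diffs]
    removed = [len(d.per_type[entity_type].removed) for d in diffs]
    jac = [d.per_type[entity_type].jaccard for d in diffs]
    return (
        statistics.fmean(added),
        statistics.fmean(removed),
        statistics.fmean(jac),
    )


@dataclass(frozen=True)
class DashboardStats:
    n_processed: int
    n_discarded: int
    n_emailed: int
    n_complete: int
    n_partial: int
    response_rate: float
    entity_count_histograms: Mapping[EntityType, Mapping[int, int]]
    mean_genes_per_nonempty_submission: float | None


def dashboard_stats(
    reports: Sequence[RunReport], submissions: Sequence[Submission]
) -> DashboardStats:
    """Monitoring statistics over one or more batch runs.

    ``response_rate`` = complete submissions / papers for which an email
    was sent (discarded papers are excluded from the denominator).
    """
    processed_ids: set[str] = set()
    n_discarded = 0
    n_emailed = 0
    histograms: dict[EntityType, Counter[int]] = {t: Counter() for t in EntityType}
    for report in reports:
        for decision in report.decisions:
            if decision.status is TriageStatus.PROCESSED:
                processed_ids.add(decision.paper_id)
            else:
                n_discarded += 1
        n_emailed += len(report.notifications)
        for extraction in report.extractions:
            for entity_type in EntityType:
                histograms[entity_type][
                    len(extraction.included.get(entity_type, ()))
                ] += 1

    n_complete = n_partial = 0
    gene_counts: list[int] = []
    for sub in submissions:
        if sub.paper_id not in processed_ids:
            raise ValidationError(
                f"submission for unknown paper {sub.paper_id!r}"
            )
        if sub.status == "complete":
            n_complete += 1
        else:
            n_partial += 1
        if sub.gene_count() > 0:
            gene_counts.append(sub.gene_count())

    return DashboardStats(
        n_processed=len(processed_ids),
        n_discarded=n_discarded,
        n_emailed=n_emailed,
        n_complete=n_complete,
        n_partial=n_partial,
        response_rate=(n_complete / n_emailed) if n_emailed else 0.0,
        entity_count_histograms={t: dict(h) for t, h in histograms.items()},
        mean_genes_per_nonempty_submission=(
            statistics.fmean(gene_counts) if gene_counts else None
        ),
    )


# ---------------------------------------------------------------------------
# Submission JSON I/O
# ---------------------------------------------------------------------------

def _submission_to_dict(sub: Submission) -> dict:
    return {
        "paper_id": sub.paper_id,
        "person_id": sub.person_id,
        "status": sub.status,
        "final_entities": {
            t.value: sorted(ids) for t, ids in sub.final_entities.items()
        },
        "flag_answers": {l.value: v for l, v in sub.flag_answers.items()},
        "manual_datatype_answers": dict(sub.manual_datatype_answers),
        "manual_entities": {
            k: list(v) for k, v in sub.manual_entities.items()
        },
        "comments": sub.comments,
    }


def _submission_from_dict(record: Mapping) -> Submission:
    return Submission(
        paper_id=record["paper_id"],
        person_id=record.get("person_id", ""),
        status=record["status"],
        final_entities={
            EntityType(t): frozenset(ids)
            for t, ids in record.get("final_entities", {}).items()
        },
        flag_answers={
            DataTypeLabel(l): bool(v)
            for l, v in record.get("flag_answers", {}).items()
        },
        manual_datatype_answers=dict(record.get("manual_datatype_answers", {})),
        manual_entities={
            k: tuple(v) for k, v in record.get("manual_entities", {}).items()
        },
        comments=record.get("comments", ""),
    )


def load_submissions(path: str | Path) -> list[Submission]:
    payload = json.loads(Path(path).read_text("utf-8"))
    return [_submission_from_dict(r) for r in payload]


def save_submissions(submissions: Iterable[Submission], path: str | Path) -> None:
    payload = [_submission_to_dict(s) for s in submissions]
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False, sort_keys=True), "utf-8"
    )
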