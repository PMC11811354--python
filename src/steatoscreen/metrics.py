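"""Turnaround-time and throughput statistics from orchestrator event logs.

Turnaround time (TAT) for a study is the time from receipt of its first
DICOM instance to completion of the last export, decomposed as

    transfer_time   = last instance received - first instance received
    processing_time = all exports done       - last instance received
    tat             = transfer_time + processing_time   (exact, by construction)

all in minutes.  Studies without both export events have no TAT and are
counted in the failure category instead.

The eligibility funnel counts studies at each pipeline stage and reports the
stage-over-stage percentages rounded to the nearest integer (half away from
zero).  In the file-drop emulation the procedure-code gate runs on the
server, so ``eligible_by_code`` counts the studies received and
``transferred`` counts those passing the code gate (i.e. entering technical
evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reporting import round_half_away
from .routing import RejectionReason

__all__ = [
    "TATRecord",
    "FunnelCounts",
    "compute_tat",
    "tat_summary",
    "funnel_report",
    "funnel_from_logs",
]

RECEIVE = "INSTANCE_RECEIVED"
COMPLETE = "STUDY_COMPLETE"
ROUTING = "ROUTING_DONE"
ALGO_START = "ALGO_START"
ALGO_END = "ALGO_END"
EXPORT_PACS = "EXPORT_PACS_DONE"
EXPORT_REPORT = "EXPORT_REPORT_DONE"
EXPORT_FAILED = "EXPORT_FAILED"
DELETED = "DELETED"


@dataclass(frozen=True)
class TATRecord:
    study_uid: str
    transfer_time: float  # minutes
    processing_time: float  # minutes
    tat: float  # minutes

    def __post_init__(self) -> None:
        if min(self.transfer_time, self.processing_time, self.tat) < 0:
            raise ValueError("TAT components must be non-negative")


@dataclass(frozen=True)
class FunnelCounts:
    eligible_by_code: int
    transferred: int
    rejected_technical: int
    selected: int
    completed: int
    exported: int

    def __post_init__(self) -> None:
        if self.transferred > self.eligible_by_code:
            raise ValueError("transferred > eligible_by_code")
        if self.rejected_technical + self.selected != self.transferred:
            raise ValueError("rejected_technical + selected != transferred")
        if self.completed > self.selected:
            raise ValueError("completed > selected")
        if self.exported > self.completed:
            raise ValueError("exported > completed")


class MissingExportError(ValueError):
    """Study has no complete export record; it has no TAT."""


def compute_tat(events: Sequence) -> TATRecord:
    """TAT decomposition for one study's ordered event list.

    ``events`` are objects (or mappings) with ``event``, ``timestamp`` and
    ``study_uid`` fields; timestamps are datetimes.
    """

    def get(e, name):
        return e[name] if isinstance(e, Mapping) else getattr(e, name)

    received = [get(e, "timestamp") for e in events if get(e, "event") == RECEIVE]
    exports_pacs = [get(e, "timestamp") for e in events if get(e, "event") == EXPORT_PACS]
    exports_rep = [get(e, "timestamp") for e in events if get(e, "event") == EXPORT_REPORT]
    if not received:
        raise MissingExportError("no INSTANCE_RECEIVED events")
    if not exports_pacs or not exports_rep:
        raise MissingExportError("missing export-done events")
    study_uid = get(events[0], "study_uid")
    first, last = min(received), max(received)
    done = max(max(exports_pacs), max(exports_rep))
    transfer = (last - first).total_seconds() / 60.0
    processing = (done - last).total_seconds() / 60.0
    return TATRecord(study_uid, transfer, processing, transfer + processing)


def tat_summary(records: Sequence[TATRecord], threshold: float = 5.0) -> dict:
    """Means, strict-threshold fraction and maximum over a TAT set.

    Values are full precision; display formatting (1 decimal) is the
    caller's concern.
    """
    if not records:
        raise ValueError("no TAT records")
    n = len(records)
    return {
        "n": n,
        "mean_transfer_min": sum(r.transfer_time for r in records) / n,
        "mean_processing_min": sum(r.processing_time for r in records) / n,
        "mean_tat_min": sum(r.tat for r in records) / n,
        "fraction_under_threshold": sum(1 for r in records if r.tat < threshold) / n,
        "max_tat_min": max(r.tat for r in records),
    }


def _stage_pct(num: int, den: int) -> float | None:
    if den == 0:
        return None  # undefined, never 0
    return round_half_away(100.0 * num / den)


def funnel_report(counts: FunnelCounts) -> dict[str, float | None]:
    """Stage-over-stage percentages, rounded half away from zero.

    A stage with zero denominator reports ``None`` (undefined), never 0.
    """
    return {
        "transferred_pct": _stage_pct(counts.transferred, counts.eligible_by_code),
        "rejected_technical_pct": _stage_pct(counts.rejected_technical, counts.transferred),
        "selected_pct": _stage_pct(counts.selected, counts.transferred),
        "completed_pct": _stage_pct(counts.completed, counts.selected),
        "exported_pct": _stage_pct(counts.exported, counts.completed),
    }


def funnel_from_logs(
    events: Iterable,
    routing_records: Iterable[Mapping],
) -> FunnelCounts:
    """Derive funnel counts from event logs plus routing records.

    ``routing_records`` are mappings with ``study_uid``, ``eligible`` and
    ``reasons`` (the serialized RoutingDecision).  Validation: an export
    event for a study with no completed analysis is an inconsistency and
    raises with the offending study UIDs.
    """

    def get(e, name):
        return e[name] if isinstance(e, Mapping) else getattr(e, name)

    by_study: dict[str, set[str]] = {}
    for e in events:
        by_study.setdefault(get(e, "study_uid"), set()).add(get(e, "event"))

    routing = {r["study_uid"]: r for r in routing_records}

    bad = sorted(
        uid
        for uid, evs in by_study.items()
        if (EXPORT_PACS in evs or EXPORT_REPORT in evs) and ALGO_END not in evs
    )
    if bad:
        raise ValueError(f"export without completed analysis for studies: {bad}")

    received = set(by_study) | set(routing)
    wrong_cpt = {
        uid
        for uid, r in routing.items()
        if RejectionReason.WRONG_CPT in tuple(r.get("reasons", ()))
    }
    transferred = received - wrong_cpt
    selected = {uid for uid, r in routing.items() if r.get("eligible")}
    rejected_technical = transferred - selected
    completed = {uid for uid in selected if ALGO_END in by_study.get(uid, set())}
    exported = {
        uid
        for uid in completed
        if {EXPORT_PACS, EXPORT_REPORT} <= by_study.get(uid, set())
    }
    return FunnelCounts(
        eligible_by_code=len(received),
        transferred=len(transferred),
        rejected_technical=len(rejected_technical),
        selected=len(selected),
        completed=len(completed),
        exported=len(exported),
    )
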