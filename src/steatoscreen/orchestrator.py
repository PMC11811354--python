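"""The runtime tying the stages together: ingest, route, analyze, export, retain.

Production systems receive studies over DICOM networking and learn about
study completion from an HL7 message; this desk-scale runtime emulates both
with a file drop-box: an inbox directory holds one folder of ``.dcm`` files
per study, and completion is signalled either by a sentinel file
(``study.complete``, mirroring the HL7 trigger) or by quiescence (no new
instance for a configured interval).

Per study, the pipeline is: assemble series -> routing decision -> (if
eligible) segmentation + steatosis analysis -> CDE packaging -> QC overlay
series to the PACS outbox and DICOM-SR to the reporting outbox -> append-only
database row.  Exports are all-or-nothing: either both artifact sets land in
their outboxes (possibly after retries) or the study is in the failed
category and nothing remains half-exported.  Every step appends a timestamped
event to a JSON-lines log, from which the metrics module computes turnaround
times and the eligibility funnel.  Imaging data is deleted by a retention
sweep after a configurable delay (default one week); derived artifacts,
database rows and logs are never swept.

Processing is single-worker and exactly-once: re-scanning an inbox never
reprocesses a study that already has a terminal state.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import shutil
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from . import dicom_io, overlay, reporting, routing, steatosis
from .dicom_io import SeriesStack
from .metrics import (
    ALGO_END,
    ALGO_START,
    COMPLETE,
    DELETED,
    EXPORT_FAILED,
    EXPORT_PACS,
    EXPORT_REPORT,
    RECEIVE,
    ROUTING,
)

__all__ = ["OrchestratorConfig", "StudyEventLog", "Event", "Orchestrator"]

logger = logging.getLogger("steatoscreen")

SENTINEL = "study.complete"


@dataclass(frozen=True)
class Event:
    study_uid: str
    event: str
    timestamp: _dt.datetime
    detail: dict = field(default_factory=dict)


class StudyEventLog:
    """Append-only, per-study time-ordered event log with JSONL persistence."""

    def __init__(self, path: Path | None = None):
        self.path = path
        self.events: list[Event] = []
        if path is not None and path.exists():
            for line in path.read_text().splitlines():
                d = json.loads(line)
                self.events.append(
                    Event(
                        d["study_uid"],
                        d["event"],
                        _dt.datetime.fromisoformat(d["timestamp"]),
                        d.get("detail", {}),
                    )
                )

    def append(
        self,
        study_uid: str,
        event: str,
        timestamp: _dt.datetime,
        detail: dict | None = None,
    ) -> Event:
        last = self.last_timestamp(study_uid)
        if last is not None and timestamp < last:
            timestamp = last  # clamp: per-study timestamps are non-decreasing
        ev = Event(study_uid, event, timestamp, detail or {})
        self.events.append(ev)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "study_uid": ev.study_uid,
                            "event": ev.event,
                            "timestamp": ev.timestamp.isoformat(),
                            "detail": ev.detail,
                        }
                    )
                    + "\n"
                )
        return ev

    def last_timestamp(self, study_uid: str) -> _dt.datetime | None:
        ts = [e.timestamp for e in self.events if e.study_uid == study_uid]
        return max(ts) if ts else None

    def for_study(self, study_uid: str) -> list[Event]:
        return [e for e in self.events if e.study_uid == study_uid]


@dataclass
class OrchestratorConfig:
    inbox: Path
    pacs_outbox: Path
    report_outbox: Path
    work_dir: Path  # state, logs, database, staging
    completion_mode: str = "signal_file"  # or "quiescence"
    quiescence_seconds: float = 2.0
    retention_days: float = 7.0
    max_retries: int = 3
    retry_backoff: tuple[float, ...] = (0.5, 1.0, 2.0)  # seconds between attempts
    segmenter: str = "fallback"  # fallback | masks-on-disk
    report_template: str = reporting.DEFAULT_TEMPLATE
    routing: routing.RoutingConfig = field(default_factory=routing.RoutingConfig)
    steatosis: steatosis.SteatosisConfig = field(default_factory=steatosis.SteatosisConfig)
    style: overlay.OverlayStyle = field(default_factory=overlay.OverlayStyle)

    def __post_init__(self) -> None:
        if self.retention_days < 0:
            raise ValueError("retention_days must be >= 0")
        if self.completion_mode not in ("signal_file", "quiescence"):
            raise ValueError("completion_mode must be signal_file or quiescence")
        dirs = [Path(self.inbox), Path(self.pacs_outbox), Path(self.report_outbox), Path(self.work_dir)]
        if len({d.resolve() for d in dirs}) != 4:
            raise ValueError("inbox, outboxes and work_dir must be distinct")
        self.inbox, self.pacs_outbox, self.report_outbox, self.work_dir = dirs

    @classmethod
    def from_toml(cls, path: str | Path) -> "OrchestratorConfig":
        raw = tomllib.loads(Path(path).read_text())
        base = Path(path).parent
        kwargs: dict = {}
        for key in ("inbox", "pacs_outbox", "report_outbox", "work_dir"):
            kwargs[key] = (base / raw[key]).resolve()
        for key in (
            "completion_mode",
            "quiescence_seconds",
            "retention_days",
            "max_retries",
            "segmenter",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "retry_backoff" in raw:
            kwargs["retry_backoff"] = tuple(raw["retry_backoff"])
        if "routing" in raw:
            r = dict(raw["routing"])
            if "eligible_cpt_codes" in r:
                r["eligible_cpt_codes"] = frozenset(r["eligible_cpt_codes"])
            kwargs["routing"] = routing.RoutingConfig(**r)
        if "steatosis" in raw:
            kwargs["steatosis"] = steatosis.SteatosisConfig(**raw["steatosis"])
        if "style" in raw:
            s = dict(raw["style"])
            if "palette" in s:
                s["palette"] = {k: tuple(v) for k, v in s["palette"].items()}
            kwargs["style"] = overlay.OverlayStyle(**s)
        if "report_template" in raw:
            kwargs["report_template"] = (base / raw["report_template"]).read_text()
        return cls(**kwargs)


def _default_transport(paths: Sequence[Path], dest: Path) -> None:
    """Copy artifacts into an outbox; the seam where transfer faults occur."""
    dest.mkdir(parents=True, exist_ok=True)
    for p in paths:
        shutil.copy2(p, dest / p.name)


class Orchestrator:
    """Single-worker pipeline over a file drop-box inbox.

    ``clock`` and ``transport`` are injectable for testing: the clock stamps
    processing events and drives quiescence/retention decisions; the
    transport performs outbox copies and is where transfer failures surface.
    ``sleeper`` replaces ``time.sleep`` for retry backoff.
    """

    def __init__(
        self,
        config: OrchestratorConfig,
        *,
        clock: Callable[[], _dt.datetime] | None = None,
        transport: Callable[[Sequence[Path], Path], None] | None = None,
        sleeper: Callable[[float], None] = time.sleep,
    ):
        self.config = config
        self.clock = clock or (lambda: _dt.datetime.now(_dt.timezone.utc))
        self.transport = transport or _default_transport
        self.sleeper = sleeper
        work = config.work_dir
        work.mkdir(parents=True, exist_ok=True)
        self.log = StudyEventLog(work / "events.jsonl")
        self.routing_path = work / "routing.jsonl"
        self.db_path = work / "database.csv"
        self.state_path = work / "processed.json"
        self.state: dict[str, dict] = (
            json.loads(self.state_path.read_text()) if self.state_path.exists() else {}
        )

    # -- state -------------------------------------------------------------

    def _save_state(self) -> None:
        self.state_path.write_text(json.dumps(self.state, indent=2))

    def _mark(self, study_uid: str, status: str, **extra) -> None:
        self.state[study_uid] = {
            "status": status,
            "finished_at": self.clock().isoformat(),
            **extra,
        }
        self._save_state()

    # -- completion detection ----------------------------------------------

    def detect_completion(self, study_dir: Path) -> bool:
        """Is this study fully received?

        ``signal_file`` mode: a sentinel file in the study folder (the HL7
        study-complete trigger, emulated).  ``quiescence`` mode: no new
        instance for ``quiescence_seconds``.
        """
        instances = list(study_dir.glob("*.dcm"))
        if not instances:
            return False
        if self.config.completion_mode == "signal_file":
            return (study_dir / SENTINEL).exists()
        newest = max(p.stat().st_mtime for p in instances)
        age = self.clock().timestamp() - newest
        return age >= self.config.quiescence_seconds

    # -- processing --------------------------------------------------------

    def scan_inbox(self) -> list[str]:
        """Process every complete, not-yet-processed study; exactly-once."""
        processed = []
        for study_dir in sorted(p for p in self.config.inbox.iterdir() if p.is_dir()):
            uid = study_dir.name
            if uid in self.state:
                self._check_late_arrival(study_dir)
                continue
            if not self.detect_completion(study_dir):
                continue
            self.process_study(study_dir)
            processed.append(uid)
        return processed

    def _check_late_arrival(self, study_dir: Path) -> None:
        uid = study_dir.name
        seen = self.state[uid].get("n_instances")
        now_count = len(list(study_dir.glob("*.dcm")))
        if seen is not None and now_count > seen:
            logger.warning("late-arriving instance(s) for processed study %s", uid)
            self.log.append(
                uid,
                RECEIVE,
                self.clock(),
                {"late_arrival": True, "n_instances": now_count},
            )
            self.state[uid]["n_instances"] = now_count
            self._save_state()

    def _segmenter(self, study_dir: Path):
        if self.config.segmenter == "fallback":
            return steatosis.fallback_segment
        if self.config.segmenter == "masks-on-disk":
            mask_path = study_dir.parent / f"{study_dir.name}.truth" / "masks.npz"
            return steatosis.masks_on_disk_segmenter(mask_path)
        raise ValueError(f"unknown segmenter {self.config.segmenter!r}")

    def process_study(self, study_dir: str | Path) -> dict:
        """Run the full pipeline on one complete study directory.

        Returns a summary record.  Ineligible studies produce a routing
        record and no algorithm events; segmentation or export failure marks
        the study failed with no partial exports.
        """
        study_dir = Path(study_dir)
        uid = study_dir.name
        if uid in self.state:
            return self.state[uid]

        instances = dicom_io.read_study(study_dir)
        for meta, _ in instances:
            self.log.append(uid, RECEIVE, meta.received_at, {"sop_uid": meta.sop_uid})
        self.log.append(uid, COMPLETE, self.clock(), {"n_instances": len(instances)})

        by_series: dict[str, list] = {}
        for inst in instances:
            by_series.setdefault(inst[0].series_uid, []).append(inst)
        stacks: list[SeriesStack] = []
        for series in by_series.values():
            if len(series) >= 2:
                stacks.append(dicom_io.assemble_series(series))

        decision = routing.select_series(stacks, self.config.routing)
        self._record_routing(decision, uid)
        self.log.append(
            uid,
            ROUTING,
            self.clock(),
            {
                "eligible": decision.eligible,
                "reasons": list(decision.reasons),
                "selected_series_uid": decision.selected_series_uid,
            },
        )
        if not decision.eligible:
            self._mark(uid, "ineligible", n_instances=len(instances))
            return self.state[uid]

        stack = next(s for s in stacks if s.series_uid == decision.selected_series_uid)
        self.log.append(uid, ALGO_START, self.clock(), {"algorithm": "hepatic_steatosis"})
        try:
            liver_mask, spleen_mask = self._segmenter(study_dir)(stack)
            result = steatosis.analyze_masks(
                stack, liver_mask, spleen_mask, self.config.steatosis
            )
        except steatosis.SegmentationError as exc:
            logger.error("segmentation failed for %s: %s", uid, exc)
            self._mark(uid, "failed", reason=str(exc), n_instances=len(instances))
            return self.state[uid]
        self.log.append(uid, ALGO_END, self.clock(), {"algorithm": "hepatic_steatosis"})

        cdes = reporting.build_cde_set(result, self.config.steatosis.hu_rounding)
        report_text = reporting.render_report(self.config.report_template, cdes)

        staging = self.config.work_dir / "staging" / uid
        if staging.exists():
            shutil.rmtree(staging)
        qc_paths = overlay.render_qc_series(
            stack,
            {"liver": liver_mask, "spleen": spleen_mask},
            self.config.style,
            staging / "qc",
        )
        sr_path = reporting.build_sr(cdes, stack.meta, staging / "sr" / "report.sr.dcm")
        (staging / "report.txt").write_text(report_text)

        ok = self._export_all(uid, qc_paths, [sr_path, staging / "report.txt"])
        if not ok:
            self._mark(uid, "export_failed", n_instances=len(instances))
            return self.state[uid]

        self.append_database(cdes, result, decision)
        self._mark(uid, "exported", n_instances=len(instances))
        return self.state[uid]

    def _record_routing(self, decision: routing.RoutingDecision, uid: str) -> None:
        with self.routing_path.open("a") as fh:
            fh.write(
                json.dumps(
                    {
                        "study_uid": uid,
                        "eligible": decision.eligible,
                        "selected_series_uid": decision.selected_series_uid,
                        "reasons": list(decision.reasons),
                    }
                )
                + "\n"
            )

    # -- exports -----------------------------------------------------------

    def _export_with_retry(self, uid: str, paths: Sequence[Path], dest: Path, kind: str) -> bool:
        attempts = 1 + max(0, self.config.max_retries)
        for attempt in range(1, attempts + 1):
            try:
                self.transport(paths, dest)
            except Exception as exc:
                self.log.append(
                    uid,
                    EXPORT_FAILED,
                    self.clock(),
                    {"kind": kind, "attempt": attempt, "error": str(exc)},
                )
                if attempt < attempts:
                    backoff = self.config.retry_backoff
                    self.sleeper(backoff[min(attempt - 1, len(backoff) - 1)] if backoff else 0.0)
                continue
            self.log.append(
                uid,
                EXPORT_PACS if kind == "pacs" else EXPORT_REPORT,
                self.clock(),
                {"kind": kind, "attempt": attempt, "n_files": len(paths)},
            )
            return True
        return False

    def _export_all(self, uid: str, qc_paths: Sequence[Path], report_paths: Sequence[Path]) -> bool:
        """Export QC then SR; on permanent failure roll back so nothing is
        half-exported."""
        if not self._export_with_retry(uid, qc_paths, self.config.pacs_outbox, "pacs"):
            return False
        if not self._export_with_retry(uid, report_paths, self.config.report_outbox, "report"):
            for p in qc_paths:  # roll back the already-landed QC files
                target = self.config.pacs_outbox / p.name
                target.unlink(missing_ok=True)
            return False
        return True

    def retry_exports(self) -> dict[str, str]:
        """Re-attempt exports for studies in the export_failed category."""
        outcomes = {}
        for uid, record in list(self.state.items()):
            if record.get("status") != "export_failed":
                continue
            staging = self.config.work_dir / "staging" / uid
            qc_paths = sorted((staging / "qc").glob("*.dcm"))
            report_paths = [staging / "sr" / "report.sr.dcm", staging / "report.txt"]
            if self._export_all(uid, qc_paths, report_paths):
                self._mark(uid, "exported", n_instances=record.get("n_instances"))
                outcomes[uid] = "exported"
            else:
                outcomes[uid] = "export_failed"
        return outcomes

    # -- database ----------------------------------------------------------

    def append_database(
        self,
        cdes: reporting.CDESet,
        result: steatosis.SteatosisResult,
        decision: routing.RoutingDecision,
    ) -> bool:
        """Append one row of unrounded values; duplicate appends are rejected."""
        uid = decision.study_uid
        if self.db_path.exists():
            existing = pd.read_csv(self.db_path, dtype={"study_uid": str})
            if uid in set(existing["study_uid"]):
                logger.warning("duplicate database append rejected for %s", uid)
                return False
        row = pd.DataFrame(
            [
                {
                    "study_uid": uid,
                    "series_uid": decision.selected_series_uid,
                    "processed_at": self.clock().isoformat(),
                    "liver_mean_hu": result.liver_mean_hu,
                    "spleen_mean_hu": result.spleen_mean_hu,
                    "shad": result.shad,
                    "liver_minus_spleen_hu": result.liver_minus_spleen_hu,
                    "liver_volume_ml": result.liver_volume_ml,
                    "steatosis_present": result.steatosis_present,
                    "liver_voxels": result.voxel_counts["liver"],
                    "spleen_voxels": result.voxel_counts["spleen"],
                    "routing_eligible": decision.eligible,
                }
            ]
        )
        row.to_csv(self.db_path, mode="a", header=not self.db_path.exists(), index=False)
        return True

    # -- retention ----------------------------------------------------------

    def retention_sweep(self, now: _dt.datetime | None = None) -> list[str]:
        """Delete imaging data for studies finished more than
        ``retention_days`` ago; derived artifacts, rows and logs survive."""
        now = now or self.clock()
        cutoff = _dt.timedelta(days=self.config.retention_days)
        deleted = []
        for uid, record in self.state.items():
            if record.get("deleted"):
                continue
            finished = _dt.datetime.fromisoformat(record["finished_at"])
            if now - finished < cutoff:
                continue
            study_dir = self.config.inbox / uid
            if study_dir.exists():
                shutil.rmtree(study_dir)
            staging = self.config.work_dir / "staging" / uid
            if staging.exists():
                shutil.rmtree(staging)
            record["deleted"] = True
            self.log.append(uid, DELETED, now, {"retention_days": self.config.retention_days})
            deleted.append(uid)
        if deleted:
            self._save_state()
        return deleted
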