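"""Orchestrator runtime: completion detection, end-to-end processing,
export retry semantics, retention, and exactly-once guarantees."""

import datetime as dt
import json

import pandas as pd
import pytest

from steatoscreen.metrics import ALGO_END, ALGO_START, DELETED, EXPORT_FAILED, RECEIVE
from steatoscreen.orchestrator import SENTINEL, Orchestrator
from steatoscreen.phantom import PhantomConfig, generate_phantom, make_scenario

from conftest import EPOCH


def drop_study(env, scenario="steatotic", seed=1, complete=True, **overrides):
    import dataclasses

    config = dataclasses.replace(make_scenario(scenario, seed=seed), **overrides)
    study_dir, truth = generate_phantom(config, env.inbox)
    if complete:
        (study_dir / SENTINEL).touch()
    return study_dir, truth


class TestCompletionDetection:
    def test_sentinel_marks_complete(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env, complete=False)
        orch = env.orchestrator()
        assert not orch.detect_completion(study_dir)
        (study_dir / SENTINEL).touch()
        assert orch.detect_completion(study_dir)

    def test_quiescence_mode(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env, complete=False)
        orch = env.orchestrator(completion_mode="quiescence", quiescence_seconds=2.0)
        env.now = dt.datetime.now(dt.timezone.utc)
        assert not orch.detect_completion(study_dir)  # just written
        env.now = env.now + dt.timedelta(seconds=10)
        assert orch.detect_completion(study_dir)  # last receipt long ago

    def test_late_arrival_is_logged_not_reprocessed(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        orch = env.orchestrator()
        orch.scan_inbox()
        rows_before = len(pd.read_csv(orch.db_path))
        # a straggler instance lands after processing
        late = study_dir / "straggler.dcm"
        late.write_bytes((sorted(study_dir.glob("*.dcm"))[0]).read_bytes())
        orch.scan_inbox()
        assert len(pd.read_csv(orch.db_path)) == rows_before
        late_events = [
            e
            for e in orch.log.for_study(study_dir.name)
            if e.event == RECEIVE and e.detail.get("late_arrival")
        ]
        assert len(late_events) == 1


class TestProcessStudy:
    def test_steatotic_end_to_end(self, orchestrator_env):
        env = orchestrator_env
        study_dir, truth = drop_study(env)
        orch = env.orchestrator()
        record = orch.process_study(study_dir)
        assert record["status"] == "exported"
        # QC series in the PACS outbox, one instance per slice
        assert len(list(env.pacs.glob("*.dcm"))) == 10
        # SR plus rendered report text in the reporting outbox
        assert len(list(env.report.glob("*.dcm"))) == 1
        report = (env.report / "report.txt").read_text()
        assert "Hepatic steatosis: present" in report
        # database row with unrounded values
        db = pd.read_csv(orch.db_path)
        assert len(db) == 1
        assert db.loc[0, "study_uid"] == study_dir.name
        assert bool(db.loc[0, "steatosis_present"])
        assert db.loc[0, "liver_volume_ml"] == truth.liver_volume_ml

    def test_ineligible_study_has_no_algorithm_events(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env, scenario="wrong_cpt")
        orch = env.orchestrator()
        record = orch.process_study(study_dir)
        assert record["status"] == "ineligible"
        events = {e.event for e in orch.log.for_study(study_dir.name)}
        assert ALGO_START not in events and ALGO_END not in events
        routing = [json.loads(l) for l in orch.routing_path.read_text().splitlines()]
        assert routing[0]["reasons"] == ["WRONG_CPT"]
        assert not env.pacs.exists() or not list(env.pacs.glob("*.dcm"))

    def test_segmentation_failure_means_no_exports(self, orchestrator_env):
        env = orchestrator_env
        # organs below the minimum component volume -> fallback cannot find two organs
        from steatoscreen.phantom import Ellipsoid

        study_dir, _ = drop_study(
            env,
            liver_ellipsoid=Ellipsoid((4.5, 32.0, 22.0), (1.0, 2.0, 2.0)),
            spleen_ellipsoid=Ellipsoid((4.5, 30.0, 50.0), (1.0, 2.0, 2.0)),
        )
        orch = env.orchestrator()
        record = orch.process_study(study_dir)
        assert record["status"] == "failed"
        assert not env.pacs.exists() or not list(env.pacs.glob("*.dcm"))
        assert not env.report.exists() or not list(env.report.glob("*"))
        events = {e.event for e in orch.log.for_study(study_dir.name)}
        assert ALGO_START in events and ALGO_END not in events

    def test_masks_on_disk_segmenter_mode(self, orchestrator_env):
        env = orchestrator_env
        study_dir, truth = drop_study(env)
        orch = env.orchestrator(segmenter="masks-on-disk")
        record = orch.process_study(study_dir)
        assert record["status"] == "exported"
        db = pd.read_csv(orch.db_path)
        assert db.loc[0, "liver_voxels"] == int(truth.liver_mask.sum())


class TestExportRetry:
    def flaky_transport(self, fail_times):
        calls = {"n": 0}

        def transport(paths, dest):
            calls["n"] += 1
            if calls["n"] <= fail_times:
                raise OSError("simulated network error")
            from steatoscreen.orchestrator import _default_transport

            _default_transport(paths, dest)

        return transport, calls

    def test_transient_failure_retried_and_logged(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        transport, calls = self.flaky_transport(fail_times=1)
        orch = env.orchestrator(transport=transport, max_retries=3)
        record = orch.process_study(study_dir)
        assert record["status"] == "exported"
        events = [e.event for e in orch.log.for_study(study_dir.name)]
        assert events.count(EXPORT_FAILED) == 1
        assert len(list(env.pacs.glob("*.dcm"))) == 10

    def test_zero_retries_means_single_attempt(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        transport, calls = self.flaky_transport(fail_times=10_000)
        orch = env.orchestrator(transport=transport, max_retries=0)
        record = orch.process_study(study_dir)
        assert record["status"] == "export_failed"
        assert calls["n"] == 1  # the PACS leg attempted exactly once, then stop

    def test_no_partial_exports_on_permanent_report_failure(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)

        def transport(paths, dest):
            if dest == env.report:
                raise OSError("reporting engine unreachable")
            from steatoscreen.orchestrator import _default_transport

            _default_transport(paths, dest)

        orch = env.orchestrator(transport=transport, max_retries=1)
        record = orch.process_study(study_dir)
        assert record["status"] == "export_failed"
        # QC files that had landed were rolled back
        assert list(env.pacs.glob("*.dcm")) == []

    def test_retry_exports_recovers_failed_study(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        transport, _ = self.flaky_transport(fail_times=10_000)
        orch = env.orchestrator(transport=transport, max_retries=0)
        assert orch.process_study(study_dir)["status"] == "export_failed"
        # the network comes back: a fresh orchestrator over the same state
        orch2 = env.orchestrator()
        outcomes = orch2.retry_exports()
        assert outcomes == {study_dir.name: "exported"}
        assert len(list(env.pacs.glob("*.dcm"))) == 10
        assert orch2.state[study_dir.name]["status"] == "exported"


class TestRetention:
    @pytest.mark.parametrize(
        "days_elapsed, retention, deleted",
        [(8, 7.0, True), (6, 7.0, False), (0, 0.0, True)],
    )
    def test_sweep_boundaries(self, orchestrator_env, days_elapsed, retention, deleted):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        orch = env.orchestrator(retention_days=retention)
        orch.process_study(study_dir)
        swept = orch.retention_sweep(now=EPOCH + dt.timedelta(days=days_elapsed))
        assert (study_dir.name in swept) is deleted
        assert study_dir.exists() is not deleted

    def test_derived_artifacts_survive_the_sweep(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        orch = env.orchestrator(retention_days=0.0)
        orch.process_study(study_dir)
        swept = orch.retention_sweep(now=EPOCH + dt.timedelta(days=1))
        assert swept == [study_dir.name]
        assert len(list(env.pacs.glob("*.dcm"))) == 10  # QC series retained
        assert (env.report / "report.txt").exists()
        assert orch.db_path.exists() and len(pd.read_csv(orch.db_path)) == 1
        assert any(e.event == DELETED for e in orch.log.for_study(study_dir.name))

    def test_unprocessed_studies_never_deleted(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env, complete=False)
        orch = env.orchestrator(retention_days=0.0)
        swept = orch.retention_sweep(now=EPOCH + dt.timedelta(days=30))
        assert swept == [] and study_dir.exists()


class TestExactlyOnce:
    def test_double_scan_processes_once(self, orchestrator_env):
        env = orchestrator_env
        drop_study(env, seed=1)
        drop_study(env, seed=2)
        orch = env.orchestrator()
        first = orch.scan_inbox()
        second = orch.scan_inbox()
        assert len(first) == 2 and second == []
        assert len(pd.read_csv(orch.db_path)) == 2

    def test_duplicate_database_append_rejected(self, orchestrator_env):
        env = orchestrator_env
        study_dir, _ = drop_study(env)
        orch = env.orchestrator()
        orch.process_study(study_dir)
        db = pd.read_csv(orch.db_path)
        row = db.iloc[0]
        from steatoscreen.routing import RoutingDecision
        from steatoscreen.reporting import build_cde_set
        from steatoscreen.steatosis import SteatosisResult

        result = SteatosisResult(
            row.liver_mean_hu,
            row.spleen_mean_hu,
            row.shad,
            row.liver_volume_ml,
            bool(row.steatosis_present),
            {"liver": 1, "spleen": 1},
        )
        decision = RoutingDecision(row.study_uid, True, row.series_uid)
        assert orch.append_database(build_cde_set(result), result, decision) is False
        assert len(pd.read_csv(orch.db_path)) == 1

    def test_rerun_on_same_inbox_is_deterministic(self, orchestrator_env, tmp_path):
        env = orchestrator_env
        drop_study(env, seed=1)
        drop_study(env, scenario="normal", seed=2)
        orch1 = env.orchestrator()
        orch1.scan_inbox()

        from steatoscreen.orchestrator import Orchestrator, OrchestratorConfig

        alt = OrchestratorConfig(
            inbox=env.inbox,
            pacs_outbox=tmp_path / "pacs2",
            report_outbox=tmp_path / "report2",
            work_dir=tmp_path / "work2",
        )
        orch2 = Orchestrator(alt, clock=env.clock)
        orch2.scan_inbox()

        drop = ["processed_at"]
        db1 = pd.read_csv(orch1.db_path).drop(columns=drop).sort_values("study_uid")
        db2 = pd.read_csv(orch2.db_path).drop(columns=drop).sort_values("study_uid")
        pd.testing.assert_frame_equal(db1.reset_index(drop=True), db2.reset_index(drop=True))
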