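"""Turnaround-time decomposition and the eligibility funnel."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steatoscreen.metrics import (
    ALGO_END,
    ALGO_START,
    EXPORT_PACS,
    EXPORT_REPORT,
    RECEIVE,
    FunnelCounts,
    MissingExportError,
    TATRecord,
    compute_tat,
    funnel_from_logs,
    funnel_report,
    tat_summary,
)

T0 = dt.datetime(2024, 1, 1, tzinfo=dt.timezone.utc)


def ev(event, seconds, uid="s1"):
    return {"study_uid": uid, "event": event, "timestamp": T0 + dt.timedelta(seconds=seconds)}


class TestComputeTAT:
    def test_hand_computed_decomposition(self):
        events = [
            ev(RECEIVE, 0),
            ev(RECEIVE, 90),
            ev(EXPORT_PACS, 170),
            ev(EXPORT_REPORT, 174),
        ]
        rec = compute_tat(events)
        assert rec.transfer_time == pytest.approx(1.5)
        assert rec.processing_time == pytest.approx(1.4)
        assert rec.tat == pytest.approx(2.9)

    def test_single_instance_zero_tat(self):
        events = [ev(RECEIVE, 0), ev(EXPORT_PACS, 0), ev(EXPORT_REPORT, 0)]
        rec = compute_tat(events)
        assert (rec.transfer_time, rec.processing_time, rec.tat) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "events",
        [
            [ev(RECEIVE, 0), ev(EXPORT_PACS, 10)],  # report export missing
            [ev(RECEIVE, 0), ev(EXPORT_REPORT, 10)],  # PACS export missing
            [ev(EXPORT_PACS, 0), ev(EXPORT_REPORT, 0)],  # no receipts
        ],
    )
    def test_incomplete_studies_have_no_tat(self, events):
        with pytest.raises(MissingExportError):
            compute_tat(events)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        receipts=st.lists(st.floats(0, 3600), min_size=1, max_size=20),
        lag_pacs=st.floats(0, 3600),
        lag_report=st.floats(0, 3600),
    )
    def test_tat_is_always_the_component_sum(self, receipts, lag_pacs, lag_report):
        last = max(receipts)
        events = [ev(RECEIVE, s) for s in receipts]
        events.append(ev(EXPORT_PACS, last + lag_pacs))
        events.append(ev(EXPORT_REPORT, last + lag_report))
        rec = compute_tat(events)
        # independent oracle: direct subtraction of the defining timestamps
        transfer = (last - min(receipts)) / 60.0
        processing = max(lag_pacs, lag_report) / 60.0
        assert rec.tat == pytest.approx(rec.transfer_time + rec.processing_time, abs=1e-12)
        assert rec.transfer_time == pytest.approx(transfer, abs=1e-6)
        assert rec.processing_time == pytest.approx(processing, abs=1e-6)


class TestTATSummary:
    def rec(self, tat, uid="s"):
        return TATRecord(uid, 0.0, tat, tat)

    def test_means_and_fraction(self):
        summary = tat_summary([self.rec(2.0), self.rec(4.0)], threshold=5.0)
        assert summary["mean_tat_min"] == 3.0
        assert summary["fraction_under_threshold"] == 1.0
        assert summary["max_tat_min"] == 4.0

    def test_threshold_is_strictly_less_than(self):
        records = [self.rec(4.9), self.rec(5.0), self.rec(5.1)]
        summary = tat_summary(records, threshold=5.0)
        assert summary["fraction_under_threshold"] == pytest.approx(1 / 3)

    def test_mean_matches_independent_resummation(self):
        rng = np.random.default_rng(6)
        tats = rng.lognormal(mean=1.0, sigma=0.5, size=1000)
        records = [self.rec(float(t), uid=f"s{i}") for i, t in enumerate(tats)]
        summary = tat_summary(records)
        # oracle: numpy's pairwise-summation mean on the raw array
        assert summary["mean_tat_min"] == pytest.approx(float(np.mean(tats)), rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tat_summary([])


class TestFunnelReport:
    def test_printed_cohort_counts_reproduce_printed_percentages(self):
        counts = FunnelCounts(3178, 2697, 1706, 991, 991, 784)
        assert funnel_report(counts) == {
            "transferred_pct": 85,
            "rejected_technical_pct": 63,
            "selected_pct": 37,
            "completed_pct": 100,
            "exported_pct": 79,
        }

    def test_all_equal_counts_give_100_everywhere(self):
        counts = FunnelCounts(7, 7, 0, 7, 7, 7)
        assert all(v == 100 for k, v in funnel_report(counts).items() if k != "rejected_technical_pct")

    def test_zero_denominator_is_undefined_not_zero(self):
        counts = FunnelCounts(5, 0, 0, 0, 0, 0)
        report = funnel_report(counts)
        assert report["transferred_pct"] == 0
        assert report["rejected_technical_pct"] is None
        assert report["selected_pct"] is None

    @pytest.mark.parametrize(
        "bad",
        [
            (3, 4, 2, 2, 2, 2),  # transferred > eligible
            (5, 4, 1, 2, 2, 2),  # rejected + selected != transferred
            (5, 4, 2, 2, 3, 2),  # completed > selected
            (5, 4, 2, 2, 2, 3),  # exported > completed
        ],
    )
    def test_invariant_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            FunnelCounts(*bad)


class TestFunnelFromLogs:
    def routing(self, uid, eligible, reasons=()):
        return {"study_uid": uid, "eligible": eligible, "reasons": list(reasons)}

    def full_run(self, uid, exported=True):
        events = [
            ev(RECEIVE, 0, uid),
            ev(ALGO_START, 10, uid),
            ev(ALGO_END, 20, uid),
        ]
        if exported:
            events += [ev(EXPORT_PACS, 30, uid), ev(EXPORT_REPORT, 31, uid)]
        return events

    def test_mixed_inbox_counts(self):
        events, routing = [], []
        for i in range(3):  # wrong CPT: routed, never analyzed
            uid = f"cpt{i}"
            events.append(ev(RECEIVE, 0, uid))
            routing.append(self.routing(uid, False, ["WRONG_CPT"]))
        for i in range(2):  # technical rejection
            uid = f"thk{i}"
            events.append(ev(RECEIVE, 0, uid))
            routing.append(self.routing(uid, False, ["NONUNIFORM_THICKNESS"]))
        for i in range(5):  # processed and exported
            uid = f"ok{i}"
            events += self.full_run(uid)
            routing.append(self.routing(uid, True))
        counts = funnel_from_logs(events, routing)
        assert counts == FunnelCounts(10, 7, 2, 5, 5, 5)

    def test_empty_logs_are_all_zero(self):
        assert funnel_from_logs([], []) == FunnelCounts(0, 0, 0, 0, 0, 0)

    def test_one_failed_export_among_five(self):
        events, routing = [], []
        for i in range(5):
            uid = f"s{i}"
            events += self.full_run(uid, exported=(i != 0))
            routing.append(self.routing(uid, True))
        counts = funnel_from_logs(events, routing)
        assert counts.completed == 5 and counts.exported == 4

    def test_export_without_analysis_is_inconsistent(self):
        events = [ev(RECEIVE, 0, "ghost"), ev(EXPORT_PACS, 5, "ghost"), ev(EXPORT_REPORT, 6, "ghost")]
        with pytest.raises(ValueError, match="ghost"):
            funnel_from_logs(events, [self.routing("ghost", True)])


def test_funnel_counts_from_real_orchestrator_logs(orchestrator_env):
    """A mixed scenario inbox: 3 wrong-CPT, 2 nonuniform, 5 eligible."""
    import json

    from test_orchestrator import drop_study

    env = orchestrator_env
    seed = 100
    for i in range(3):
        drop_study(env, scenario="wrong_cpt", seed=seed + i)
    for i in range(2):
        drop_study(env, scenario="nonuniform_thickness", seed=seed + 10 + i)
    for i in range(5):
        drop_study(env, scenario="steatotic", seed=seed + 20 + i)
    orch = env.orchestrator()
    orch.scan_inbox()
    routing_records = [json.loads(l) for l in orch.routing_path.read_text().splitlines()]
    counts = funnel_from_logs(orch.log.events, routing_records)
    assert counts == FunnelCounts(10, 7, 2, 5, 5, 5)
    report = funnel_report(counts)
    assert report["completed_pct"] == 100 and report["exported_pct"] == 100
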