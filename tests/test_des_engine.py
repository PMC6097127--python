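import numpy as np
import pytest

from taktclinic.clinic_model import (ClinicConfig, Department, Pathway,
                                     ServiceModel)
from taktclinic.demand import ArrivalStream, sample_arrivals
from taktclinic.des_engine import (CAPACITY_CHANGE, END_SERVICE, ENTER_QUEUE,
                                   EXIT_CLINIC, START_SERVICE,
                                   PredictivePolicy, SimulationError,
                                   StaticPolicy, effective_capacity, simulate)
from taktclinic.takt_planner import ResourcePlan, build_static_plan

from conftest import single_department_clinic


def events_of(log, etype):
    return [e for e in log.events if e.event_type == etype]


class TestLindleyTrace:
    def test_waits_and_cycles_follow_lindley_recursion(self, lindley_setup):
        clinic, stream, plan = lindley_setup
        log = simulate(clinic, stream, StaticPolicy(plan), seed=0)
        starts = {e.patient_id: e.time for e in events_of(log, START_SERVICE)}
        exits = {e.patient_id: e.time for e in events_of(log, EXIT_CLINIC)}
        # W_{n+1} = max(0, W_n + S - A): waits 0, 3, 6
        assert starts == {0: 0.0, 1: 5.0, 2: 10.0}
        assert exits == {0: 5.0, 1: 10.0, 2: 15.0}

    def test_flush_serves_everyone_after_close(self, lindley_setup):
        clinic, stream, plan = lindley_setup
        log = simulate(clinic, stream, StaticPolicy(plan), seed=0)
        # last exit at t=15 even though the stream ends well before
        assert len(events_of(log, EXIT_CLINIC)) == 3


class TestStructure:
    def test_empty_stream_logs_only_capacity_changes(self, small_bundle):
        log = simulate(small_bundle.clinic, ArrivalStream(()),
                       StaticPolicy(small_bundle.static_plan()), seed=1)
        assert log.events
        assert all(e.event_type == CAPACITY_CHANGE for e in log.events)

    def test_arrivals_conserved(self, small_bundle):
        stream = sample_arrivals(small_bundle.profile, small_bundle.clinic, 5)
        log = simulate(small_bundle.clinic, stream,
                       StaticPolicy(small_bundle.static_plan()), seed=5)
        assert len(events_of(log, "arrive")) == len(stream)
        assert len(events_of(log, EXIT_CLINIC)) == len(stream)

    def test_fifo_order_per_department(self, small_bundle):
        stream = sample_arrivals(small_bundle.profile, small_bundle.clinic, 7)
        log = simulate(small_bundle.clinic, stream,
                       StaticPolicy(small_bundle.static_plan()), seed=7)
        for dept in small_bundle.clinic.department_ids:
            queue_order = [e.patient_id for e in log.events
                           if e.event_type == ENTER_QUEUE
                           and e.department_id == dept]
            start_order = [e.patient_id for e in log.events
                           if e.event_type == START_SERVICE
                           and e.department_id == dept]
            assert start_order == queue_order

    def test_in_service_never_exceeds_capacity(self, small_bundle):
        stream = sample_arrivals(small_bundle.profile, small_bundle.clinic, 9)
        log = simulate(small_bundle.clinic, stream,
                       StaticPolicy(small_bundle.static_plan()), seed=9)
        busy = {d: 0 for d in small_bundle.clinic.department_ids}
        cap = {d: 0 for d in small_bundle.clinic.department_ids}
        for e in log.events:
            if e.event_type == CAPACITY_CHANGE:
                cap[e.detail[0]] = e.detail[1]
            elif e.event_type == START_SERVICE:
                busy[e.department_id] += 1
                assert busy[e.department_id] <= cap[e.department_id]
            elif e.event_type == END_SERVICE:
                busy[e.department_id] -= 1

    def test_determinism_same_seed_byte_identical(self, small_bundle):
        stream = sample_arrivals(small_bundle.profile, small_bundle.clinic, 3)
        pol = PredictivePolicy(small_bundle.profile)
        a = simulate(small_bundle.clinic, stream, pol, seed=3)
        b = simulate(small_bundle.clinic, stream, pol, seed=3)
        assert a.events_jsonl() == b.events_jsonl()

    def test_unknown_arrival_class_rejected(self, small_bundle):
        bad = ArrivalStream(((1.0, "ghost"),))
        with pytest.raises(SimulationError):
            simulate(small_bundle.clinic, bad,
                     StaticPolicy(small_bundle.static_plan()), seed=1)


class TestCapacityChange:
    def make_two_slot_clinic(self):
        # two 4-min slots; capacity drops 2 -> 1 at t=4
        clinic = single_department_clinic(8.0, 2,
                                          ServiceModel("deterministic", 5.0))
        clinic = ClinicConfig(clinic.departments, clinic.pathways,
                              0.0, 8.0, 4.0)
        counts = np.array([[2], [1]])
        eff = np.array([[0.0], [4.0]])
        plan = ResourcePlan(counts, eff, np.array([0.0, 4.0]), ("Q",),
                            "static")
        return clinic, plan

    def test_capacity_drop_never_preempts(self):
        clinic, plan = self.make_two_slot_clinic()
        stream = ArrivalStream(((0.0, "p"), (0.0, "p"), (4.5, "p")))
        log = simulate(clinic, stream, StaticPolicy(plan), seed=0)
        ends = {e.patient_id: e.time for e in events_of(log, END_SERVICE)}
        starts = {e.patient_id: e.time for e in events_of(log, START_SERVICE)}
        # both in-flight services run to completion through the drop at t=4
        assert ends[0] == 5.0 and ends[1] == 5.0
        # the third patient must wait for a release, then only 1 server
        assert starts[2] == 5.0 and ends[2] == 10.0

    def test_effective_capacity_respects_mid_slot_effective_from(self):
        counts = np.array([[2], [2], [2], [3]])
        eff = np.array([[0.0], [30.0], [60.0], [105.0]])  # change mid-slot
        plan = ResourcePlan(counts, eff, np.array([0.0, 30.0, 60.0, 90.0]),
                            ("Q",), "predictive")
        assert effective_capacity(plan, "Q", 100.0) == 2
        assert effective_capacity(plan, "Q", 105.0) == 3
        # flush: last value persists past the end of the day
        assert effective_capacity(plan, "Q", 500.0) == 3

    def test_static_plan_capacity_constant(self, small_bundle):
        plan = small_bundle.static_plan()
        for d in small_bundle.clinic.department_ids:
            caps = {effective_capacity(plan, d, t)
                    for t in (0.0, 31.0, 65.0, 119.0)}
            assert len(caps) == 1


class TestRandomness:
    def test_departments_use_independent_substreams(self):
        # identical service models, same seed: draws differ across depts
        a = Department("A", ServiceModel("exponential", 5.0), max_resources=4)
        b = Department("B", ServiceModel("exponential", 5.0), max_resources=4)
        clinic = ClinicConfig((a, b), (Pathway("w", ("A", "B"), 1.0),),
                              0.0, 120.0, 30.0)
        plan = build_static_plan(clinic, {"A": 4, "B": 4})
        stream = ArrivalStream(tuple((float(i), "w") for i in range(10)))
        log = simulate(clinic, stream, StaticPolicy(plan), seed=12)
        from taktclinic.metrics import service_sequences
        seqs = service_sequences(log)
        assert seqs["A"] != seqs["B"]
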