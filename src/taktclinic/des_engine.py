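"""Future-event-list simulation of patient flow through the clinic.

Each department is a FIFO multi-server queue whose server count follows the
effective resource plan.  Patients traverse their pathway's departments in
order; after closing time no new arrivals occur but everyone already inside
is served to completion (the flush).  A capacity decrease never preempts: a
removed server finishes its current patient, then retires.

Simultaneous events are ordered end_service < replan < capacity_change <
arrive < start_service, with patient id as the final tie-break, so freed
servers are released before new seizes at the same instant and every run is
deterministic.  Service times come from an independent random substream per
(seed, department), so two policies simulated with the same seed see the
same per-department draw sequences (common random numbers).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from collections import deque
from pathlib import Path

import numpy as np

from .clinic_model import ClinicConfig
from .demand import ArrivalProfile, ArrivalStream, forecast_demand
from .takt_planner import ResourcePlan, build_resource_plan, replan as replan_op

ARRIVE = "arrive"
ENTER_QUEUE = "enter_queue"
START_SERVICE = "start_service"
END_SERVICE = "end_service"
EXIT_CLINIC = "exit_clinic"
CAPACITY_CHANGE = "capacity_change"

JOIN_MARKER = "JOIN"
EXIT_MARKER = "EXIT"

# same-instant processing priorities
_P_END, _P_REPLAN, _P_CAPEVAL, _P_ARRIVE = 0, 1, 2, 3


class SimulationError(ValueError):
    pass


@dataclass(slots=True)
class SimEvent:
    time: float
    patient_id: int  # -1 for capacity_change
    department_id: str
    event_type: str
    detail: tuple | None = None

    def to_dict(self) -> dict:
        d = {"time": self.time, "patient_id": self.patient_id,
             "department_id": self.department_id,
             "event_type": self.event_type}
        if self.detail is not None:
            d["detail"] = list(self.detail)
        return d


@dataclass
class EventLog:
    events: list[SimEvent]
    clinic: ClinicConfig
    seed: int
    policy: dict
    final_plan: ResourcePlan | None = None  # plan in force at day end

    def events_jsonl(self) -> str:
        return "\n".join(json.dumps(e.to_dict()) for e in self.events)

    def to_jsonl(self, path: str | Path) -> None:
        Path(path).write_text(self.events_jsonl() + "\n")

    @staticmethod
    def read_events_jsonl(path: str | Path) -> list[SimEvent]:
        out = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            det = d.get("detail")
            out.append(SimEvent(d["time"], d["patient_id"],
                                d["department_id"], d["event_type"],
                                None if det is None else tuple(det)))
        return out


# ----------------------------------------------------------------------
# Policies
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StaticPolicy:
    """Run the whole day on one fixed plan (typically constant staffing)."""

    plan: ResourcePlan

    def describe(self) -> dict:
        return {"kind": "static", "plan_provenance": self.plan.provenance}


@dataclass(frozen=True)
class PredictivePolicy:
    """Replan every ``replan_interval`` minutes with a ``reaction_time`` lag.

    The initial day plan defaults to one built in advance from the profile
    forecast; pass ``initial_plan`` to start from e.g. the static baseline.
    """

    profile: ArrivalProfile
    forecast_method: str = "rolling_empirical"
    reaction_time: float = 0.0
    replan_interval: float | None = None  # defaults to the slot length
    initial_plan: ResourcePlan | None = None

    def describe(self) -> dict:
        return {"kind": "predictive",
                "plan_provenance": "predictive",
                "forecast": self.forecast_method,
                "reaction_time": self.reaction_time,
                "replan_interval": self.replan_interval}


Policy = StaticPolicy | PredictivePolicy


# ----------------------------------------------------------------------
# Capacity as a function of time
# ----------------------------------------------------------------------

def effective_capacity(plan: ResourcePlan, department_id: str,
                       time: float) -> int:
    """Capacity in force at ``time``: the latest plan cell whose
    ``effective_from`` is <= time; the last slot's value persists through the
    end-of-day flush."""
    j = plan.department_ids.index(department_id)
    eff = plan.effective_from[:, j]
    order = np.argsort(eff, kind="stable")
    cap = int(plan.counts[order[0], j])
    for s in order:
        if eff[s] <= time:
            cap = int(plan.counts[s, j])
        else:
            break
    return cap


def _capacity_tables(plan: ResourcePlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-department (sorted effective_from, counts) step functions."""
    tables = []
    for j in range(len(plan.department_ids)):
        eff = plan.effective_from[:, j]
        order = np.argsort(eff, kind="stable")
        tables.append((eff[order], plan.counts[order, j].astype(int)))
    return tables


# ----------------------------------------------------------------------
# The simulator
# ----------------------------------------------------------------------

@dataclass(slots=True)
class _Dept:
    idx: int
    id: str
    queue: deque
    busy: int
    capacity: int
    rng: np.random.Generator
    model: object  # ServiceModel


def simulate(clinic: ClinicConfig, stream: ArrivalStream, policy: Policy,
             seed: int) -> EventLog:
    """Run one clinic day and return the complete event log."""
    day = clinic.day_length
    for t, _ in stream.events:
        if not 0 <= t < day:
            raise SimulationError(f"arrival at t={t} outside [0, {day})")
    class_steps = {p.class_id: tuple(p.steps) for p in clinic.pathways}
    dep_index = {d.id: j for j, d in enumerate(clinic.departments)}

    if isinstance(policy, StaticPolicy):
        plan = policy.plan
    else:
        policy.profile.validate_against(clinic)
        plan = policy.initial_plan
        if plan is None:
            f0 = forecast_demand(ArrivalStream(()), policy.profile, clinic,
                                 0.0, method="profile")
            plan = build_resource_plan(f0, clinic)
    if plan.department_ids != clinic.department_ids:
        raise SimulationError("plan departments do not match the clinic")
    if plan.n_slots != clinic.n_slots:
        raise SimulationError("plan slot grid does not match the clinic")

    depts = [
        _Dept(j, d.id, deque(), 0, 0,
              np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(j,))),
              d.service_model)
        for j, d in enumerate(clinic.departments)
    ]
    cap_tables = _capacity_tables(plan)

    def capacity_at(j: int, t: float) -> int:
        eff, cnt = cap_tables[j]
        k = int(np.searchsorted(eff, t, side="right")) - 1
        return int(cnt[max(k, 0)])

    log: list[SimEvent] = []
    heap: list[tuple] = []
    seq = 0

    def push(t: float, prio: int, tb: int, kind: str, a: int = 0) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, prio, tb, seq, kind, a))
        seq += 1

    # patients
    steps_of: list[tuple[int, ...]] = []
    arrive_time: list[float] = []
    step_pos: list[int] = []
    for pid, (t, cls) in enumerate(stream.events):
        if cls not in class_steps:
            raise SimulationError(f"arrival class {cls!r} not in clinic pathways")
        steps_of.append(tuple(dep_index[s] for s in class_steps[cls]))
        arrive_time.append(t)
        step_pos.append(0)
        push(t, _P_ARRIVE, pid, "arrive", pid)

    # initial capacities at t=0
    for d in depts:
        d.capacity = capacity_at(d.idx, 0.0)
        log.append(SimEvent(0.0, -1, d.id, CAPACITY_CHANGE,
                            (d.id, d.capacity)))

    def schedule_breakpoints(now: float) -> None:
        times: set[float] = set()
        for eff, _cnt in cap_tables:
            for t in eff:
                if t > now:
                    times.add(float(t))
        for t in sorted(times):
            push(t, _P_CAPEVAL, -1, "capeval")

    schedule_breakpoints(0.0)

    if isinstance(policy, PredictivePolicy):
        interval = policy.replan_interval or clinic.slot_length
        if not interval > 0:
            raise SimulationError("replan_interval must be > 0")
        t = 0.0
        while t < day:
            push(t, _P_REPLAN, -1, "replan")
            t += interval

    dirty: set[int] = set()

    def enqueue(pid: int, j: int, t: float) -> None:
        d = depts[j]
        log.append(SimEvent(t, pid, d.id, ENTER_QUEUE))
        d.queue.append(pid)
        dirty.add(j)

    def handle(t: float, kind: str, a: int, tb: int) -> None:
        nonlocal plan, cap_tables
        if kind == "end":
            pid, j = tb, a
            d = depts[j]
            log.append(SimEvent(t, pid, d.id, END_SERVICE))
            d.busy -= 1
            dirty.add(j)
            step_pos[pid] += 1
            steps = steps_of[pid]
            if step_pos[pid] < len(steps):
                enqueue(pid, steps[step_pos[pid]], t)
            else:
                log.append(SimEvent(t, pid, EXIT_MARKER, EXIT_CLINIC))
        elif kind == "replan":
            assert isinstance(policy, PredictivePolicy)
            observed = (stream if policy.forecast_method == "oracle"
                        else stream.truncated(t))
            fc = forecast_demand(observed, policy.profile, clinic, t,
                                 method=policy.forecast_method)
            plan = replan_op(plan, fc, policy.reaction_time, t, clinic)
            cap_tables = _capacity_tables(plan)
            push(t, _P_CAPEVAL, -1, "capeval")
            schedule_breakpoints(t)
        elif kind == "capeval":
            for d in depts:
                cap = capacity_at(d.idx, t)
                if cap != d.capacity:
                    d.capacity = cap
                    log.append(SimEvent(t, -1, d.id, CAPACITY_CHANGE,
                                        (d.id, cap)))
                    dirty.add(d.idx)
        else:  # arrive
            pid = a
            log.append(SimEvent(t, pid, JOIN_MARKER, ARRIVE))
            enqueue(pid, steps_of[pid][0], t)

    while heap:
        t = heap[0][0]
        while heap and heap[0][0] == t:
            _, _, tb, _, kind, a = heapq.heappop(heap)
            handle(t, kind, a, tb)
        # dispatch: seize free servers for waiting patients, FIFO
        for j in sorted(dirty):
            d = depts[j]
            while d.queue and d.busy < d.capacity:
                pid = d.queue.popleft()
                dur = d.model.sample(d.rng)
                log.append(SimEvent(t, pid, d.id, START_SERVICE))
                d.busy += 1
                push(t + dur, _P_END, pid, "end", j)
        dirty.clear()

    return EventLog(events=log, clinic=clinic, seed=seed,
                    policy=policy.describe(), final_plan=plan)
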