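"""KPIs from event logs: waiting time, cycle time, utilization, and
policy-vs-policy reductions.

Waiting time is the total time a patient spends in queues across all visited
departments (service excluded); cycle time is the full sojourn from arrival
to exit.  Standard deviations are population SDs (divide by n) — the paper
of record for lean methods reports spread to flag unregulated waiting, and
at clinic scale the n vs n-1 distinction is immaterial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .des_engine import (ARRIVE, CAPACITY_CHANGE, END_SERVICE, ENTER_QUEUE,
                         EXIT_CLINIC, START_SERVICE, EventLog)
from .takt_planner import ResourcePlan


class LogIntegrityError(ValueError):
    """The event log violates the per-patient event grammar."""


@dataclass
class _PatientTrace:
    arrive: float | None = None
    exit: float | None = None
    wait: float = 0.0
    service: float = 0.0
    pending_queue: tuple[str, float] | None = None  # (dept, enter time)
    in_service: tuple[str, float] | None = None


def _traces(log: EventLog) -> dict[int, _PatientTrace]:
    traces: dict[int, _PatientTrace] = {}
    last_t = -math.inf
    for ev in log.events:
        if ev.time < last_t - 1e-12:
            raise LogIntegrityError("event times decrease")
        last_t = max(last_t, ev.time)
        if ev.event_type == CAPACITY_CHANGE:
            continue
        tr = traces.setdefault(ev.patient_id, _PatientTrace())
        if ev.event_type == ARRIVE:
            if tr.arrive is not None:
                raise LogIntegrityError(f"patient {ev.patient_id} arrives twice")
            tr.arrive = ev.time
        elif ev.event_type == ENTER_QUEUE:
            if tr.arrive is None or tr.pending_queue or tr.in_service:
                raise LogIntegrityError(
                    f"patient {ev.patient_id}: enter_queue out of order")
            tr.pending_queue = (ev.department_id, ev.time)
        elif ev.event_type == START_SERVICE:
            if not tr.pending_queue or tr.pending_queue[0] != ev.department_id:
                raise LogIntegrityError(
                    f"patient {ev.patient_id}: start_service without queue")
            tr.wait += ev.time - tr.pending_queue[1]
            tr.pending_queue = None
            tr.in_service = (ev.department_id, ev.time)
        elif ev.event_type == END_SERVICE:
            if not tr.in_service or tr.in_service[0] != ev.department_id:
                raise LogIntegrityError(
                    f"patient {ev.patient_id}: end_service without start")
            tr.service += ev.time - tr.in_service[1]
            tr.in_service = None
        elif ev.event_type == EXIT_CLINIC:
            if tr.exit is not None or tr.in_service or tr.pending_queue:
                raise LogIntegrityError(
                    f"patient {ev.patient_id}: bad exit")
            tr.exit = ev.time
    return traces


def _exited(log: EventLog) -> list[tuple[int, _PatientTrace]]:
    return sorted(((pid, tr) for pid, tr in _traces(log).items()
                   if tr.exit is not None))


def waiting_times(log: EventLog) -> np.ndarray:
    """Total queue wait per exited patient, in patient-id order."""
    return np.array([tr.wait for _, tr in _exited(log)])


def cycle_times(log: EventLog) -> np.ndarray:
    """Arrival-to-exit sojourn per exited patient, in patient-id order."""
    return np.array([tr.exit - tr.arrive for _, tr in _exited(log)])


def service_sequences(log: EventLog) -> dict[str, list[float]]:
    """Per-department service durations in start-service order (the order the
    random substream was consumed) — used for common-random-number checks."""
    starts: dict[tuple[int, str], float] = {}
    order: dict[str, list[tuple[int, str]]] = {}
    durations: dict[tuple[int, str], float] = {}
    for ev in log.events:
        key = (ev.patient_id, ev.department_id)
        if ev.event_type == START_SERVICE:
            starts[key] = ev.time
            order.setdefault(ev.department_id, []).append(key)
        elif ev.event_type == END_SERVICE:
            durations[key] = ev.time - starts[key]
    return {d: [durations[k] for k in keys] for d, keys in order.items()}


@dataclass
class KpiReport:
    """One run's KPIs; KPI fields are NaN when no patient exited."""

    n_patients: int
    mean_wait: float
    sd_wait: float
    mean_cycle: float
    sd_cycle: float
    dept_mean_wait: dict[str, float]
    utilization: dict[str, float]
    resource_profile: np.ndarray

    @property
    def defined(self) -> bool:
        return self.n_patients > 0

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "mean_wait": self.mean_wait, "sd_wait": self.sd_wait,
            "mean_cycle": self.mean_cycle, "sd_cycle": self.sd_cycle,
            "dept_mean_wait": dict(self.dept_mean_wait),
            "utilization": dict(self.utilization),
            "resource_profile": [int(x) for x in self.resource_profile],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv_row(self) -> dict:
        row = {"n_patients": self.n_patients, "mean_wait": self.mean_wait,
               "sd_wait": self.sd_wait, "mean_cycle": self.mean_cycle,
               "sd_cycle": self.sd_cycle}
        row.update({f"wait_{d}": v for d, v in self.dept_mean_wait.items()})
        row.update({f"util_{d}": v for d, v in self.utilization.items()})
        return row


def _capacity_minutes(log: EventLog) -> dict[str, float]:
    """Integral of each department's capacity over [0, horizon], where the
    horizon is the later of close time and the last event (flush included)."""
    horizon = log.clinic.day_length
    if log.events:
        horizon = max(horizon, log.events[-1].time)
    current: dict[str, tuple[float, int]] = {}
    total: dict[str, float] = {}
    for ev in log.events:
        if ev.event_type != CAPACITY_CHANGE:
            continue
        d, cnt = ev.detail
        if d in current:
            t0, c0 = current[d]
            total[d] = total.get(d, 0.0) + c0 * (ev.time - t0)
        total.setdefault(d, 0.0)
        current[d] = (ev.time, int(cnt))
    for d, (t0, c0) in current.items():
        total[d] += c0 * (horizon - t0)
    return total


def _busy_minutes(log: EventLog) -> dict[str, float]:
    seqs = service_sequences(log)
    return {d: float(sum(v)) for d, v in seqs.items()}


def kpi_summary(log: EventLog, plan: ResourcePlan) -> KpiReport:
    """Aggregate a completed run into one KPI report."""
    exited = _exited(log)
    n = len(exited)
    waits = np.array([tr.wait for _, tr in exited])
    cycles = np.array([tr.exit - tr.arrive for _, tr in exited])

    dept_waits: dict[str, list[float]] = {d: [] for d in plan.department_ids}
    pending: dict[tuple[int, str], float] = {}
    for ev in log.events:
        if ev.event_type == ENTER_QUEUE:
            pending[(ev.patient_id, ev.department_id)] = ev.time
        elif ev.event_type == START_SERVICE:
            t0 = pending.pop((ev.patient_id, ev.department_id))
            dept_waits.setdefault(ev.department_id, []).append(ev.time - t0)

    cap_min = _capacity_minutes(log)
    busy_min = _busy_minutes(log)
    utilization = {}
    for d in plan.department_ids:
        alloc = cap_min.get(d, 0.0)
        utilization[d] = (busy_min.get(d, 0.0) / alloc) if alloc > 0 else 0.0

    nan = float("nan")
    return KpiReport(
        n_patients=n,
        mean_wait=float(waits.mean()) if n else nan,
        sd_wait=float(waits.std()) if n else nan,  # population SD
        mean_cycle=float(cycles.mean()) if n else nan,
        sd_cycle=float(cycles.std()) if n else nan,
        dept_mean_wait={d: (float(np.mean(v)) if v else nan)
                        for d, v in dept_waits.items()},
        utilization=utilization,
        resource_profile=plan.total_per_slot(),
    )


@dataclass
class PolicyComparison:
    """Percent reductions, positive = the treatment improved on the baseline.

    A reduction is ``None`` (undefined) when the baseline KPI is zero.
    """

    mean_wait_reduction_pct: float | None
    sd_wait_reduction_pct: float | None
    mean_cycle_reduction_pct: float | None

    def to_dict(self) -> dict:
        return {"mean_wait_reduction_pct": self.mean_wait_reduction_pct,
                "sd_wait_reduction_pct": self.sd_wait_reduction_pct,
                "mean_cycle_reduction_pct": self.mean_cycle_reduction_pct}


def _reduction(base: float, treat: float) -> float | None:
    if base == 0 or math.isnan(base):
        return None
    return 100.0 * (base - treat) / base


def compare_policies(baseline: KpiReport,
                     treatment: KpiReport) -> PolicyComparison:
    if not (baseline.defined and treatment.defined):
        raise ValueError("both reports must contain at least one patient")
    return PolicyComparison(
        mean_wait_reduction_pct=_reduction(baseline.mean_wait,
                                           treatment.mean_wait),
        sd_wait_reduction_pct=_reduction(baseline.sd_wait,
                                         treatment.sd_wait),
        mean_cycle_reduction_pct=_reduction(baseline.mean_cycle,
                                            treatment.mean_cycle),
    )
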