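"""Takt-time resource planning for the whole clinic.

Takt time is the pace at which patients must leave the system for supply to
match demand: for a slot of length ``L`` minutes expecting ``D`` patients,

    T = L / D        (minutes per patient).

A department whose effective process time is ``p`` minutes per patient then
needs ``ceil(p / T) = ceil(p * D / L)`` parallel resources to keep up, clipped
to its staffing bounds.  Classic line balancing applies this to a stable,
levelled demand; here ``D`` is a stochastic short-term forecast, recomputed
during the day, and a *reaction time* limits how soon a revised allocation
can reach the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clinic_model import ClinicConfig
from .demand import DemandForecast

# Guard against float noise pushing an exact quotient over the next integer.
_CEIL_EPS = 1e-9


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class TaktResult:
    """Takt time for one slot; ``takt is None`` encodes the no-demand case."""

    takt: float | None
    slot_length: float
    demand: float

    @property
    def no_demand(self) -> bool:
        return self.takt is None


def compute_takt(slot_length: float, demand: float) -> TaktResult:
    """Takt = available time / demand; a zero-demand slot has no Takt."""
    if not slot_length > 0:
        raise PlanningError(f"slot_length must be > 0, got {slot_length}")
    if demand < 0:
        raise PlanningError(f"demand must be >= 0, got {demand}")
    if demand == 0:
        return TaktResult(takt=None, slot_length=slot_length, demand=0.0)
    return TaktResult(takt=slot_length / demand, slot_length=slot_length,
                      demand=demand)


def required_resources(effective_process_time: float, takt: TaktResult,
                       min_r: int, max_r: int) -> int:
    """Resources needed so the per-resource pace does not exceed the Takt.

    Rounds up — under-provisioning would defeat the plan — then clips to the
    department's staffing bounds.  No demand means floor staffing.
    """
    if not effective_process_time > 0:
        raise PlanningError("effective_process_time must be > 0")
    if min_r > max_r:
        raise PlanningError(f"min_r {min_r} exceeds max_r {max_r}")
    if takt.no_demand:
        return min_r
    n = math.ceil(effective_process_time / takt.takt - _CEIL_EPS)
    return int(min(max(n, min_r), max_r))


@dataclass(frozen=True)
class ResourcePlan:
    """Per-slot, per-department allocated resource counts for one day.

    ``counts[s, d]`` follows the department order of the clinic config;
    ``effective_from[s, d]`` is the earliest minute the allocation takes
    effect (slot start for a plan made in advance, later when a replan's
    reaction delay pushes it into the slot).
    """

    counts: np.ndarray          # int, shape (n_slots, n_depts)
    effective_from: np.ndarray  # float, same shape
    slot_starts: np.ndarray     # float, shape (n_slots,)
    department_ids: tuple[str, ...]
    provenance: str             # "static" | "predictive"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResourcePlan):
            return NotImplemented
        return (self.department_ids == other.department_ids
                and self.provenance == other.provenance
                and np.array_equal(self.counts, other.counts)
                and np.array_equal(self.effective_from, other.effective_from)
                and np.array_equal(self.slot_starts, other.slot_starts))

    @property
    def n_slots(self) -> int:
        return self.counts.shape[0]

    def total_per_slot(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def copy(self, provenance: str | None = None) -> "ResourcePlan":
        return ResourcePlan(self.counts.copy(), self.effective_from.copy(),
                            self.slot_starts.copy(), self.department_ids,
                            provenance or self.provenance)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (self.slot_starts[s], d, int(self.counts[s, j]),
             self.effective_from[s, j], self.provenance)
            for s in range(self.n_slots)
            for j, d in enumerate(self.department_ids)
        ]
        pd.DataFrame(rows, columns=["slot_start_min", "department_id",
                                    "count", "effective_from_min",
                                    "provenance"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResourcePlan":
        df = pd.read_csv(path)
        dept_ids = tuple(dict.fromkeys(df["department_id"].astype(str)))
        slot_starts = np.sort(df["slot_start_min"].unique().astype(float))
        S, D = len(slot_starts), len(dept_ids)
        counts = np.zeros((S, D), dtype=int)
        eff = np.zeros((S, D), dtype=float)
        slot_idx = {t: i for i, t in enumerate(slot_starts)}
        dep_idx = {d: j for j, d in enumerate(dept_ids)}
        for _, r in df.iterrows():
            s, j = slot_idx[float(r.slot_start_min)], dep_idx[str(r.department_id)]
            counts[s, j] = int(r["count"])
            eff[s, j] = float(r.effective_from_min)
        return cls(counts, eff, slot_starts, dept_ids,
                   str(df["provenance"].iloc[0]))


def department_demand(forecast_demand_s: float, clinic: ClinicConfig,
                      dept_id: str) -> float:
    """Slot demand seen by one department: class-mix-weighted pass-through."""
    return forecast_demand_s * clinic.visit_fraction(dept_id)


def build_resource_plan(forecast: DemandForecast,
                        clinic: ClinicConfig,
                        provenance: str = "predictive") -> ResourcePlan:
    """Turn a full-day demand forecast into a day's resource plan."""
    S = clinic.n_slots
    if not all(forecast.covers_slot(s) for s in range(S)):
        raise PlanningError("forecast must cover every slot of the day "
                            f"(as_of={forecast.as_of})")
    L = clinic.slot_length
    counts = np.zeros((S, len(clinic.departments)), dtype=int)
    eff = np.zeros_like(counts, dtype=float)
    for s in range(S):
        D_s = forecast.demand(s)
        for j, dept in enumerate(clinic.departments):
            d_demand = department_demand(D_s, clinic, dept.id)
            takt = compute_takt(L, d_demand)
            counts[s, j] = required_resources(dept.effective_process_time,
                                              takt, dept.min_resources,
                                              dept.max_resources)
            eff[s, j] = clinic.slot_start(s)
    return ResourcePlan(counts, eff,
                        np.array([clinic.slot_start(s) for s in range(S)]),
                        clinic.department_ids, provenance)


def build_static_plan(clinic: ClinicConfig,
                      fixed_counts: dict[str, int]) -> ResourcePlan:
    """Constant staffing all day — the conventional baseline."""
    if not clinic.departments:
        raise PlanningError("clinic has no departments")
    missing = set(clinic.department_ids) - set(fixed_counts)
    if missing:
        raise PlanningError(f"fixed_counts missing departments: {sorted(missing)}")
    row = []
    for dept in clinic.departments:
        c = int(fixed_counts[dept.id])
        if not dept.min_resources <= c <= dept.max_resources:
            raise PlanningError(
                f"fixed count {c} for {dept.id} outside "
                f"[{dept.min_resources}, {dept.max_resources}]")
        row.append(c)
    S = clinic.n_slots
    counts = np.tile(np.array(row, dtype=int), (S, 1))
    slot_starts = np.array([clinic.slot_start(s) for s in range(S)])
    eff = np.tile(slot_starts[:, None], (1, len(row))).astype(float)
    return ResourcePlan(counts, eff, slot_starts, clinic.department_ids,
                        "static")


def replan(current: ResourcePlan, forecast: DemandForecast,
           reaction_time: float, now: float,
           clinic: ClinicConfig) -> ResourcePlan:
    """Revise the remainder of the day's plan under a reaction delay.

    A slot is mutable only if it starts at or after ``now + reaction_time``
    (decision-to-deployment latency); earlier cells are frozen as currently
    planned.  Mutable cells are recomputed from the forecast exactly as in
    :func:`build_resource_plan`, with ``effective_from`` never earlier than
    ``now + reaction_time``.
    """
    if reaction_time < 0:
        raise PlanningError("reaction_time must be >= 0")
    new = current.copy(provenance="predictive")
    cutoff = now + reaction_time
    L = clinic.slot_length
    for s in range(new.n_slots):
        start = new.slot_starts[s]
        if start < cutoff:
            continue  # frozen
        if not forecast.covers_slot(s):
            raise PlanningError(f"forecast (as_of={forecast.as_of}) does not "
                                f"cover mutable slot {s}")
        D_s = forecast.demand(s)
        for j, dept in enumerate(clinic.departments):
            takt = compute_takt(L, department_demand(D_s, clinic, dept.id))
            new.counts[s, j] = required_resources(
                dept.effective_process_time, takt,
                dept.min_resources, dept.max_resources)
            new.effective_from[s, j] = max(start, cutoff)
    return new
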