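"""Domain model of an outpatient clinic (OPC).

A clinic is a set of departments visited in a fixed order by one or more
patient classes ("pathways").  The working day is divided into equal planning
slots of length ``L`` minutes; every timestamp in the package is measured in
minutes from clinic opening (t = 0 at ``open_time``).  Slot ``s`` covers the
half-open interval ``[s*L, (s+1)*L)`` on that clock, so every minute of the
day belongs to exactly one slot and ``close_time`` to none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

SCHEMA_VERSION = 1
SERVICE_FAMILIES = ("exponential", "lognormal", "deterministic")


class ClinicConfigError(ValueError):
    """Raised when a config file cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class ServiceModel:
    """Effective service-time distribution of one resource at a department.

    ``mean`` is the effective process time in minutes (> 0): the average time
    one resource needs per patient, routine disturbances included.  ``cv`` is
    the coefficient of variation, used only by the lognormal family
    (exponential has cv = 1 by construction, deterministic cv = 0).
    """

    family: str
    mean: float
    cv: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in SERVICE_FAMILIES:
            raise ClinicConfigError(
                f"service_model.family must be one of {SERVICE_FAMILIES}, "
                f"got {self.family!r}"
            )
        if not self.mean > 0:
            raise ClinicConfigError("service_model.mean must be > 0")
        if self.family == "lognormal" and not self.cv > 0:
            raise ClinicConfigError("service_model.cv must be > 0 for lognormal")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one service duration (minutes)."""
        if self.family == "exponential":
            return float(rng.exponential(self.mean))
        if self.family == "deterministic":
            return self.mean
        # lognormal parameterised by (mean, cv)
        sigma2 = math.log1p(self.cv * self.cv)
        mu = math.log(self.mean) - 0.5 * sigma2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))

    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean}
        if self.family == "lognormal":
            d["cv"] = self.cv
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ServiceModel":
        return cls(family=d["family"], mean=float(d["mean"]),
                   cv=float(d.get("cv", 1.0)))


@dataclass(frozen=True)
class Department:
    """One service station: a FIFO multi-server queue with capacity bounds."""

    id: str
    service_model: ServiceModel
    min_resources: int = 0
    max_resources: int = 1
    effective_process_time: float | None = None  # defaults to the model mean

    def __post_init__(self) -> None:
        if self.effective_process_time is None:
            object.__setattr__(self, "effective_process_time",
                               self.service_model.mean)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "service_model": self.service_model.to_dict(),
            "min_resources": self.min_resources,
            "max_resources": self.max_resources,
            "effective_process_time": self.effective_process_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Department":
        ept = d.get("effective_process_time")
        return cls(
            id=str(d["id"]),
            service_model=ServiceModel.from_dict(d["service_model"]),
            min_resources=int(d.get("min_resources", 0)),
            max_resources=int(d.get("max_resources", 1)),
            effective_process_time=None if ept is None else float(ept),
        )


@dataclass(frozen=True)
class Pathway:
    """An ordered visit sequence for one patient class.

    ``mix_fraction`` is the probability that an arriving patient belongs to
    this class; fractions over all pathways sum to 1.
    """

    class_id: str
    steps: tuple[str, ...]
    mix_fraction: float

    def to_dict(self) -> dict:
        return {"class_id": self.class_id, "steps": list(self.steps),
                "mix_fraction": self.mix_fraction}

    @classmethod
    def from_dict(cls, d: dict) -> "Pathway":
        return cls(class_id=str(d["class_id"]),
                   steps=tuple(str(s) for s in d["steps"]),
                   mix_fraction=float(d["mix_fraction"]))


@dataclass(frozen=True)
class ClinicConfig:
    """Clinic topology plus the planning-slot grid.

    ``open_time`` and ``close_time`` are minutes from midnight; everything
    downstream uses the relative clock (minutes since opening).
    """

    departments: tuple[Department, ...]
    pathways: tuple[Pathway, ...]
    open_time: float
    close_time: float
    slot_length: float
    queue_discipline: str = "FIFO"

    # -- slot grid -----------------------------------------------------

    @property
    def day_length(self) -> float:
        return self.close_time - self.open_time

    @property
    def n_slots(self) -> int:
        return int(round(self.day_length / self.slot_length))

    def slot_start(self, s: int) -> float:
        """Start of slot ``s`` on the relative clock."""
        return s * self.slot_length

    def slot_of(self, t: float) -> int:
        """Slot containing relative time ``t`` in [0, day_length)."""
        if not 0 <= t < self.day_length:
            raise ValueError(f"time {t} outside [0, {self.day_length})")
        return int(t // self.slot_length)

    @property
    def department_ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.departments)

    def department(self, dept_id: str) -> Department:
        for d in self.departments:
            if d.id == dept_id:
                return d
        raise KeyError(dept_id)

    def visit_fraction(self, dept_id: str) -> float:
        """Mix-weighted fraction of arrivals whose pathway visits ``dept_id``."""
        return sum(p.mix_fraction for p in self.pathways if dept_id in p.steps)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "clinic": {
                "open_time": self.open_time,
                "close_time": self.close_time,
                "slot_length": self.slot_length,
                "queue_discipline": self.queue_discipline,
            },
            "departments": [d.to_dict() for d in self.departments],
            "pathways": [p.to_dict() for p in self.pathways],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicConfig":
        try:
            clinic = d["clinic"]
            return cls(
                departments=tuple(Department.from_dict(x)
                                  for x in d["departments"]),
                pathways=tuple(Pathway.from_dict(x) for x in d["pathways"]),
                open_time=float(clinic["open_time"]),
                close_time=float(clinic["close_time"]),
                slot_length=float(clinic["slot_length"]),
                queue_discipline=str(clinic.get("queue_discipline", "FIFO")),
            )
        except KeyError as e:
            raise ClinicConfigError(f"missing required config field: {e}") from e

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    code: str
    field: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def codes(self) -> list[str]:
        return [i.code for i in self.issues]

    def add(self, code: str, fld: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, fld, message))

    def __str__(self) -> str:
        if self.ok:
            return "valid"
        return "; ".join(f"{i.code}[{i.field}]: {i.message}" for i in self.issues)


def validate_clinic(config: ClinicConfig) -> ValidationReport:
    """Check every structural invariant; never raises, always reports."""
    rep = ValidationReport()
    dept_ids = [d.id for d in config.departments]
    if len(set(dept_ids)) != len(dept_ids):
        rep.add("DUPLICATE_DEPARTMENT", "departments", "duplicate department ids")

    for d in config.departments:
        if not d.service_model.mean > 0:
            rep.add("NONPOSITIVE_PROCESS_TIME", f"departments.{d.id}",
                    "service mean must be > 0")
        if d.min_resources < 0 or d.max_resources < d.min_resources:
            rep.add("CAPACITY_BOUNDS", f"departments.{d.id}",
                    f"need 0 <= min ({d.min_resources}) <= max "
                    f"({d.max_resources})")
        rel = abs(d.effective_process_time - d.service_model.mean) / d.service_model.mean
        if rel > 1e-9:
            rep.add("PROCESS_TIME_MISMATCH", f"departments.{d.id}",
                    f"effective_process_time {d.effective_process_time} != "
                    f"service model mean {d.service_model.mean}")

    on_pathway: set[str] = set()
    for p in config.pathways:
        if not p.steps:
            rep.add("EMPTY_PATHWAY", f"pathways.{p.class_id}", "no steps")
        for step in p.steps:
            if step not in dept_ids:
                rep.add("UNKNOWN_DEPARTMENT", f"pathways.{p.class_id}",
                        f"step references undeclared department {step!r}")
            else:
                on_pathway.add(step)
        if not 0 <= p.mix_fraction <= 1:
            rep.add("PATHWAY_MIX_RANGE", f"pathways.{p.class_id}",
                    f"mix_fraction {p.mix_fraction} outside [0, 1]")
    if config.pathways:
        total = sum(p.mix_fraction for p in config.pathways)
        if abs(total - 1.0) > 1e-9:
            rep.add("PATHWAY_MIX_SUM", "pathways",
                    f"mix fractions sum to {total}, expected 1")
    else:
        rep.add("NO_PATHWAYS", "pathways", "at least one pathway required")

    for d in config.departments:
        if d.id in on_pathway and d.max_resources < 1:
            rep.add("DEPT_UNSTAFFABLE", f"departments.{d.id}",
                    "department on a pathway needs max_resources >= 1")

    if not config.close_time > config.open_time:
        rep.add("BAD_HOURS", "clinic",
                f"close_time {config.close_time} must exceed open_time "
                f"{config.open_time}")
    if not config.slot_length > 0:
        rep.add("BAD_SLOT_LENGTH", "clinic",
                f"slot_length {config.slot_length} must be > 0")
    elif config.close_time > config.open_time:
        ratio = (config.close_time - config.open_time) / config.slot_length
        if abs(ratio - round(ratio)) > 1e-9:
            rep.add("SLOT_GRID_MISALIGNED", "clinic",
                    f"day length {config.close_time - config.open_time} is not "
                    f"an integer multiple of slot_length {config.slot_length}")
    if config.queue_discipline != "FIFO":
        rep.add("UNSUPPORTED_DISCIPLINE", "clinic",
                f"queue_discipline {config.queue_discipline!r}; only FIFO "
                "is supported")
    return rep


def load_clinic_config(path: str | Path) -> ClinicConfig:
    """Read and validate a clinic config (YAML, or JSON with the same keys)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"clinic config not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ClinicConfigError(f"cannot parse {p}: {e}") from e
    if not isinstance(raw, dict):
        raise ClinicConfigError(f"{p}: top level must be a mapping")
    config = ClinicConfig.from_dict(raw)
    report = validate_clinic(config)
    if not report.ok:
        raise ClinicConfigError(f"invalid clinic config {p}: {report}")
    return config
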