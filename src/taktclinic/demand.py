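"""Stochastic walk-in demand: arrival streams and slot-level forecasts.

Walk-in arrivals at a high-volume clinic are overdispersed relative to a
Poisson process: some days are simply busier than others.  The generator
models this as a gamma-mixed Poisson process with a day-level busyness
factor ``G ~ Gamma(shape = dispersion, mean = 1)``: the realised intensity
of slot ``s`` is ``Λ_s = base_rates[s] * G`` — marginally
Gamma(shape = ``dispersion``, mean = ``base_rates[s]``) — and the slot count
is Poisson given ``Λ_s``, so marginally negative binomial with

    mean      = base_rates[s]
    variance  = base_rates[s] * (1 + base_rates[s] / dispersion).

Sharing ``G`` across the day couples slot counts the way real walk-in demand
is coupled (a heavy morning predicts a heavy afternoon), which is exactly
the signal the rolling short-term forecast exploits.  ``dispersion = None``
(or ``inf``) collapses the mixture to a pure Poisson process.  Arrivals are
placed uniformly within their slot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .clinic_model import ClinicConfig

FORECAST_METHODS = ("profile", "rolling_empirical", "oracle")

# rolling-forecast demand-ratio clip; guards against early-morning
# small-sample explosions
RATIO_CLIP = (0.25, 4.0)


class DemandError(ValueError):
    """Profile/stream inconsistent with the clinic slot grid."""


@dataclass(frozen=True)
class ArrivalProfile:
    """Per-slot mean arrival counts plus overdispersion and class mix."""

    base_rates: tuple[float, ...]
    dispersion: float | None = None  # gamma mixing shape; None => Poisson
    class_mix: dict[str, float] | None = None  # None => use clinic pathway mix

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.base_rates):
            raise DemandError("base_rates must be >= 0")
        if self.dispersion is not None and not self.dispersion > 0:
            raise DemandError("dispersion must be > 0")

    def validate_against(self, clinic: ClinicConfig) -> None:
        if len(self.base_rates) != clinic.n_slots:
            raise DemandError(
                f"profile has {len(self.base_rates)} slot rates but clinic "
                f"has {clinic.n_slots} slots")

    def mix_for(self, clinic: ClinicConfig) -> tuple[list[str], np.ndarray]:
        if self.class_mix is not None:
            ids = sorted(self.class_mix)
            return ids, np.array([self.class_mix[c] for c in ids])
        ids = [p.class_id for p in clinic.pathways]
        return ids, np.array([p.mix_fraction for p in clinic.pathways])

    def to_dict(self) -> dict:
        d: dict = {"base_rates": list(self.base_rates)}
        if self.dispersion is not None:
            d["dispersion"] = self.dispersion
        if self.class_mix is not None:
            d["class_mix"] = dict(self.class_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArrivalProfile":
        return cls(base_rates=tuple(float(r) for r in d["base_rates"]),
                   dispersion=(None if d.get("dispersion") is None
                               else float(d["dispersion"])),
                   class_mix=d.get("class_mix"))


@dataclass(frozen=True)
class ArrivalStream:
    """Ordered (arrival_time, class_id) events for one simulated day.

    Times are minutes since opening, in [0, day_length); the day closes to
    new arrivals at close_time.  ``seed`` records the generator seed and is
    ``None`` for empirical (CSV-loaded) streams.
    """

    events: tuple[tuple[float, str], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DemandError("arrival times must be nondecreasing")
        if times and times[0] < 0:
            raise DemandError("arrival times must be >= 0")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    def truncated(self, t: float) -> "ArrivalStream":
        """Events strictly before time ``t`` (what a planner has observed)."""
        return ArrivalStream(tuple(e for e in self.events if e[0] < t),
                             seed=self.seed)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.events,
                     columns=["arrival_time_min", "class_id"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ArrivalStream":
        df = pd.read_csv(path)
        missing = {"arrival_time_min", "class_id"} - set(df.columns)
        if missing:
            raise DemandError(f"arrival CSV missing columns: {sorted(missing)}")
        return cls(tuple(zip(df["arrival_time_min"].astype(float),
                             df["class_id"].astype(str))), seed=None)


@dataclass(frozen=True)
class DemandForecast:
    """Expected arrivals per future slot, as seen at decision epoch ``as_of``.

    ``per_slot_demand`` has one entry per clinic slot; slots that started
    before ``as_of`` are NaN (no forecast is produced for them).
    """

    as_of: float
    per_slot_demand: np.ndarray
    method: str

    def demand(self, slot: int) -> float:
        v = float(self.per_slot_demand[slot])
        if math.isnan(v):
            raise DemandError(f"slot {slot} starts before as_of={self.as_of}")
        return v

    def covers_slot(self, slot: int) -> bool:
        return not math.isnan(float(self.per_slot_demand[slot]))


def sample_arrivals(profile: ArrivalProfile, clinic: ClinicConfig,
                    seed: int) -> ArrivalStream:
    """Draw one day of arrivals from the gamma-mixed Poisson profile.

    Deterministic in (profile, clinic, seed).
    """
    profile.validate_against(clinic)
    rng = np.random.default_rng(seed)
    class_ids, mix = profile.mix_for(clinic)
    L = clinic.slot_length
    if profile.dispersion is None or math.isinf(profile.dispersion):
        busyness = 1.0
    else:
        k = profile.dispersion
        busyness = float(rng.gamma(shape=k, scale=1.0 / k))
    events: list[tuple[float, str]] = []
    for s, rate in enumerate(profile.base_rates):
        count = int(rng.poisson(rate * busyness))
        if count == 0:
            continue
        times = np.sort(rng.uniform(s * L, (s + 1) * L, size=count))
        classes = rng.choice(class_ids, size=count, p=mix / mix.sum())
        events.extend(zip(times.tolist(), classes.tolist()))
    return ArrivalStream(tuple(events), seed=seed)


def empirical_slot_counts(stream: ArrivalStream,
                          clinic: ClinicConfig) -> np.ndarray:
    """Realised integer arrival counts per slot (half-open slot intervals)."""
    counts = np.zeros(clinic.n_slots, dtype=int)
    for t, _ in stream.events:
        if not 0 <= t < clinic.day_length:
            raise DemandError(f"arrival at t={t} outside the clinic day")
        counts[int(t // clinic.slot_length)] += 1
    return counts


def _expected_so_far(profile: ArrivalProfile, clinic: ClinicConfig,
                     t: float) -> float:
    """Expected arrivals in [0, t) under the profile (partial slots prorated)."""
    L = clinic.slot_length
    total = 0.0
    for s, rate in enumerate(profile.base_rates):
        overlap = min(t, (s + 1) * L) - s * L
        if overlap <= 0:
            break
        total += rate * min(overlap, L) / L
    return total


def forecast_demand(observed: ArrivalStream, profile: ArrivalProfile,
                    clinic: ClinicConfig, t: float,
                    method: str = "profile") -> DemandForecast:
    """Forecast per-slot demand for slots starting at or after ``t``.

    * ``profile`` — the a-priori profile means.
    * ``rolling_empirical`` — profile means rescaled by the ratio of observed
      to expected arrivals so far, clipped to RATIO_CLIP (ratio 1 when
      nothing was expected yet).
    * ``oracle`` — the realised counts of the full stream (lookahead;
      ``observed`` must then be the complete day's stream).  Upper-bound
      experiments only.
    """
    if method not in FORECAST_METHODS:
        raise DemandError(
            f"unknown forecast method {method!r}; choose from {FORECAST_METHODS}")
    if not 0 <= t <= clinic.day_length:
        raise DemandError(f"decision epoch t={t} outside the clinic day")
    profile.validate_against(clinic)
    L = clinic.slot_length
    values = np.full(clinic.n_slots, np.nan)
    future = [s for s in range(clinic.n_slots) if s * L >= t]

    if method == "profile":
        for s in future:
            values[s] = profile.base_rates[s]
    elif method == "rolling_empirical":
        expected = _expected_so_far(profile, clinic, t)
        if expected > 0:
            ratio = len(observed.truncated(t)) / expected
            ratio = min(max(ratio, RATIO_CLIP[0]), RATIO_CLIP[1])
        else:
            ratio = 1.0
        for s in future:
            values[s] = profile.base_rates[s] * ratio
    else:  # oracle
        counts = empirical_slot_counts(observed, clinic)
        for s in future:
            values[s] = counts[s]
    return DemandForecast(as_of=t, per_slot_demand=values, method=method)
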