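# Methods

## Scope and clocks

`taktclinic` models one working day of a multi-department walk-in outpatient
clinic. All times are minutes, measured from clinic opening (t = 0); the day
is divided into equal planning slots of length `L`, each covering the
half-open interval `[s·L, (s+1)·L)`, so every minute belongs to exactly one
slot. Queue discipline is FIFO at every department; pathways are fixed
linear visit sequences per patient class (no mid-pathway branching — class
mix carries the heterogeneity). Staff skill mix, breaks, appointment books,
no-shows and multi-day effects are out of scope.

## Demand model

Arrivals follow a gamma-mixed Poisson process. A single day-level busyness
factor `G ~ Gamma(shape = dispersion, mean = 1)` scales the whole profile:
slot `s` has realised intensity `Λ_s = base_rates[s] · G`, count
`~ Poisson(Λ_s)`, and arrivals placed uniformly within the slot. Marginally
each slot count is negative binomial with mean `base_rates[s]` and variance
`base_rates[s]·(1 + base_rates[s]/dispersion)`. The day-level factor was
chosen over independent per-slot intensity draws deliberately: it couples
slot counts the way real walk-in demand is coupled (a heavy morning predicts
a heavy afternoon), which is the signal any short-term forecast exploits;
with independent per-slot draws the "forecastable" part of demand would be
pure noise and within-day replanning could not work even in principle.
`dispersion=None` gives a plain Poisson process (used by the queueing
oracle tests).

What the generator does **not** emulate: within-day autocorrelation beyond
the shared day factor, arrival batching (families), punctuality/appointment
structure, or weekday seasonality. Passing tests therefore show that the
planner exploits day-level demand information correctly, not that it would
capture every pattern in real HMIS feeds.

## Forecasting

Three estimators produce per-slot expected demand for slots starting at or
after the decision epoch `t`:

- `profile` — the a-priori profile means (what was known before the day);
- `rolling_empirical` — profile means rescaled by (arrivals observed in
  `[0, t)`) / (arrivals expected in `[0, t)`), the natural estimator of the
  day factor `G`; the ratio is clipped to `[0.25, 4]` to stop small-sample
  explosions in the first minutes, and defined as 1 while nothing was
  expected yet;
- `oracle` — the realised counts (lookahead), for upper-bound experiments.

The concrete estimator is this package's stand-in for whatever demand
model a clinic derives from its records; it is deliberately simple and
documented as such.

## Takt planning

For slot demand `D` the Takt time is `T = L/D` (no Takt when `D = 0`). A
department with effective process time `p` needs `ceil(p/T)` resources,
clipped to its `[min, max]` staffing bounds; zero demand falls to floor
staffing. Rounding is always up — letting the per-resource pace exceed the
Takt would under-provision by construction. The demand a department sees is
the slot demand times the mix fraction of classes visiting it, with **no
phase-lag offset**: a patient arriving in slot `s` is counted as departmental
demand in slot `s` even though they may reach downstream departments a slot
later. This is the simplest defensible choice; the simulator measures its
consequences honestly (it is one reason the predictive plan, which targets
utilisation ≈ 1 slot by slot, loses modestly to a slack baseline on quiet
days). A phase-lag correction is a listed extension, not implemented.

Replanning at time `now` with reaction time `r` may only modify slots whose
start is ≥ `now + r`; earlier cells are frozen as currently planned.
Recomputed cells take effect at their slot start. With `r` at least the day
length nothing is ever mutable, so the controller degenerates exactly to its
initial plan — the basis of the reaction-time degeneracy test.

## Simulation engine

A future-event-list simulator (binary heap). Simultaneous events are
processed in the order end_service < replan < capacity_change < arrive <
start_service, with patient id as the final tie-break: servers freed at an
instant are available to seizes at that same instant, and runs are fully
deterministic. Service durations are drawn lazily at seize time from a
per-department substream (`SeedSequence(seed, spawn_key=(dept_index,))`), so
two policies simulated with the same seed consume identical per-department
draw sequences — common random numbers for paired comparison. Capacity
decreases never preempt: a removed server finishes its patient, then
retires; capacity increases dispatch waiting patients immediately. After
closing time no arrivals occur, the last slot's capacities persist, and all
in-house patients are served to completion; their waits count in every KPI.
The default replan interval is one slot.

## KPIs

Waiting time is the sum over visited departments of (service start − queue
entry); cycle time is exit − arrival. Standard deviations are population
SDs. Utilisation is busy-server-minutes over the integral of allocated
capacity (flush period included), so it is ≤ 1 by construction. Policy
comparisons report `100·(baseline − treatment)/baseline`, positive =
improvement, undefined (None) for a zero baseline.

In the packaged studies, aggregate KPIs are pooled over *patients*:
replication days are weighted by their patient counts, and the pooled SD is
reconstructed exactly from each day's mean and SD. This matches what "the
average waiting time" means operationally (an average over patients, in
which busy days rightly weigh more) and avoids the pathology of averaging
per-day percentage reductions, which are unbounded on near-zero-wait quiet
days. The 95% CI on a pooled reduction is a delete-one-replication
jackknife; arms are paired by common random numbers.

## Benchmark clinic

A five-department eye-clinic day, 09:00–17:00, 30-minute slots:
registration (p = 2 min), vision testing (5), refraction (5), doctor
examination (8) visited by everyone, counselling (6) by a 30% class.
Service times are lognormal with cv 0.5–0.7. Mean arrivals per slot ramp
from 30 up to 44 mid-morning and tail to 10 by late afternoon (~420
patients/day); the day-level busyness factor has gamma shape 8 (cv ≈ 0.35,
a realistic day-to-day spread for clinic attendance). The static baseline
keeps 28 resources on the floor all day, split {REG 4, VIS 7, REF 6, DOC 8,
COU 3} — deliberately the *conventional* roster this method argues against:
support stations staffed generously, the expensive doctor pool pinned near
its average workload so the morning peak overloads it for hours. All of
these numbers are declared once in `experiments.py`; they are realistic
stand-ins for a high-volume clinic, not measurements of any specific one.
Default studies use 50 replications and master seed 20170972; per-
replication seeds derive from one `SeedSequence`.

The studies' problem sizes (50 replications; queueing-oracle runs of 200 ×
10,000 simulated minutes with 1,000-minute warm-up) were chosen so Monte-
Carlo error is small relative to the effects measured while the whole suite
stays quick to run.

## Numerical choices

- Ceiling computations subtract 1e-9 before `ceil` so an exact quotient is
  not pushed to the next integer by float noise.
- Validation tolerances: pathway mix sums to 1 ± 1e-9; declared effective
  process time must match the service-model mean to 1e-9 relative.
- Lognormal service models are parameterised by (mean, cv):
  `σ² = ln(1+cv²)`, `μ = ln(mean) − σ²/2`.
- Replication seeds are reduced mod 2³¹.

## Known limitations

- Planning on arrival-slot demand (no phase-lag offset) understaffs
  downstream departments on declining demand and overstaffs on rising
  demand; the effect is visible in the benchmark results.
- Takt staffing targets utilisation ≈ 1 in every slot and carries no
  queueing buffer, so the predictive plan trades higher waits on quiet days
  for large wins on busy days; the patient-pooled aggregate captures the
  net effect.
- The rolling forecast estimates only a day-level scale factor; it cannot
  anticipate within-day shape changes.
- Single-day horizon: no carry-over of demand or fatigue across days.
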