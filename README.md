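# taktclinic

Takt-time resource planning and discrete-event simulation for walk-in
outpatient clinics (OPCs) under stochastic demand.

High-volume walk-in clinics plan staffing ahead of time, department by
department, and then react late when the day turns out busier than planned —
which is exactly when waiting rooms overflow. `taktclinic` implements the
alternative: a clinic-wide **predictive resource plan** recomputed during the
day from short-term demand, paced by the **Takt time**, together with a
discrete-event simulator that quantifies how much the **reaction time** (the
lag between a replanning decision and staff actually moving) costs in patient
waiting and cycle time.

## The model

The working day is split into slots of length *L* minutes. If *D_s* patients
are expected in slot *s*, the Takt time — the pace at which patients must
leave the system for supply to match demand — is

```
T_s = L / D_s          (minutes per patient)
```

A department *d* with effective process time *p_d* (mean minutes one resource
needs per patient) then requires

```
N_{d,s} = clip( ceil(p_d / T_s), min_d, max_d ) = clip( ceil(p_d · D_s / L), … )
```

parallel resources in slot *s*, where the demand seen by *d* is the slot
demand weighted by the fraction of patient classes whose pathway visits *d*.
Demand is a gamma-mixed Poisson process (negative-binomial slot counts: some
days are simply busier), forecast during the day by rescaling the a-priori
profile with the observed-to-expected arrival ratio. A replanning decision
made at time *t* can only touch slots starting at or after *t + reaction
time*; earlier slots stay as planned.

The simulator is a deterministic future-event-list engine: each department is
a FIFO multi-server queue whose server count follows the plan in force,
capacity cuts never preempt a service in progress, the clinic closes to new
arrivals at the end of the day but serves everyone still inside, and service
times are drawn from per-department random substreams so that competing
policies can be compared under common random numbers.

## Worked example

```python
import taktclinic as tc

bundle = tc.make_benchmark_clinic("full")        # 5-department eye clinic
result = tc.static_vs_predictive(bundle, replications=50, seed=20170972)
for row in result.aggregates:
    print(row)
```

prints (abridged):

```
{'policy': 'static',     'mean_wait': 35.58, 'mean_cycle': 57.35, 'resource_min': 28, 'resource_max': 28, ...}
{'policy': 'predictive', 'mean_wait': 23.83, 'mean_cycle': 45.59, 'resource_min': 6,  'resource_max': 54, ...}
{'policy': 'reduction', 'metric': 'mean_wait',  'mean_reduction_pct': 51.41, 'ci95_lo': 35.65, 'ci95_hi': 67.18}
{'policy': 'reduction', 'metric': 'sd_wait',    'mean_reduction_pct': 57.69, 'ci95_lo': 46.08, 'ci95_hi': 69.31}
{'policy': 'reduction', 'metric': 'mean_cycle', 'mean_reduction_pct': 36.50, 'ci95_lo': 21.27, 'ci95_hi': 51.74}
```

Read: the conventional baseline keeps 28 resources on the floor all day; the
predictive plan moves between 6 and 54 as demand requires, and cuts the
patient-pooled average wait by about half (the 95% CI comes from a
delete-one-day jackknife over the 50 paired replication days). The same
machinery is available from the shell:

```bash
taktclinic simulate --scale small --seed 1 --out run/
taktclinic experiment --name reaction-sweep --replications 50 --seed 20170972 --out sweep/ --plot
```

## Layout

- `clinic_model` — departments, pathways, slot grid, config I/O + validation
- `demand` — arrival sampling, slot counts, short-term forecasts
- `takt_planner` — Takt computation, resource plans, replanning with delay
- `des_engine` — the event-list simulator and staffing policies
- `metrics` — waiting/cycle times, utilization, policy comparison
- `experiments` — benchmark clinic and the two packaged studies
- `cli` — `taktclinic simulate | experiment | validate`

See `docs/methods.md` for modelling assumptions, parameter rationale, and
limitations.
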