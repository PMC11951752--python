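# Methods

## Model

`edtsim` models the waiting list for laboratory visual electrodiagnostic
testing (EDT) at a regional referral service as a single FIFO queue with a
weekly batch service: at each integer week, up to `capacity_per_week`
patients (default 12) are taken from the head of the queue. Time is
continuous for arrivals and discrete for service; a 52-week year and
13-week quarter are used throughout, and all durations are in weeks.

Referrals arrive as independent homogeneous Poisson processes in four
groups (A–D) whose weekly rates divide a 13-week referral audit by 13:
A 77/13, B 14/13, C 40/13, D 64/13 (15/week, 780/year in total). Each
group A–C patient carries a latent gold-standard ERG status, abnormal with
probability 23/77, 4/14 and 5/40 respectively — the audit's abnormal
fractions. Group D patients are referred primarily for VEP testing, cannot
be screened with a hand-held ERG, and carry no status draw; they matter
only as laboratory demand. The audit gives only rates and proportions, so
homogeneous Poisson arrivals are the natural minimal model; no seasonality
or day-of-week structure is represented.

At time zero the waiting list already holds `backlog` patients
(default 228). Backlog patients bypass screening, join the queue at t = 0,
and are drawn from the same group mix as arrivals — a bookkeeping choice
only, since every backlog patient consumes exactly one laboratory slot
regardless of group. Waiting already accrued before time zero is credited
via `backlog_accrued_weeks` (default 0; the audit's historical mean delay
of ~13.6 weeks is a reasonable alternative and raises the 5-year mean wait
by about one week; the default keeps the model free of an otherwise
unobservable parameter).

## Screening step

The hand-held ERG screen is a binary test applied at referral to the
configured subset of groups A–C: an abnormal patient is flagged with
probability `Se` (sensitivity), a normal patient is flagged with
probability `1 − Sp` (specificity), defaults 0.95/0.95. Flagged patients
join the laboratory queue at their arrival time; cleared patients leave
the pathway permanently (re-testing of false negatives is outside the
model). Screening is instantaneous and capacity-unconstrained — the
device's point is that it needs no specialist laboratory — so no screening
queue exists. Every screen is classified TP/FP/TN/FN against the latent
truth, and per-replication counts of each class are reported. Closed-form
expectations (e.g. FN = T·Σ λ_g·p_g·(1 − Se)) are provided for
cross-checking the Monte-Carlo counts.

Screening draws come from an RNG stream separate from arrival generation,
so sensitivity/specificity sweeps see identical arrival streams (common
random numbers).

## Statistics and protocol

The headline statistic is the mean wait of patients *served* within a
reporting window (a, b] — the serving-time convention. Under the fluid
approximation (below) this convention reproduces the service's observed
windowed waits, whereas an arrival-cohort convention does not; it is also
the natural reading of "the average wait in years 1–5". Waits are
real-valued weeks internally and rounded to whole weeks only at render
time.

Each scenario cell is replicated `n_reps` times (2000 by default) under a
two-phase protocol: phase 1 simulates 260 weeks from the time-zero backlog
and reports the window (0, 260]; phase 2 is an independent 312-week run
with the same backlog reporting only (260, 312] — a 5-year warm-up whose
data are discarded, answering whether the waiting time has stabilised by
year 6. Summaries report across-replication means with standard errors and
normal-approximation 95 % CIs.

Replication i of any cell derives its backlog, arrival and screening
streams from `(base_seed, i, stream_tag)` seed sequences — deliberately
*not* keyed by the cell — so all cells run at one base seed share arrival
streams. This gives common-random-number variance reduction for scenario
contrasts by construction while keeping every cell independently
reproducible; runs are bit-identical for a fixed base seed.

## Fluid oracle

An independent analytic check treats the queue as deterministic flows:
served mass accumulates at rate c while the queue is non-empty, arrivals
at the effective rate

λ_eff = scale · [λ_D + Σ_{g screened} λ_g(p_g·Se + (1−p_g)(1−Sp)) + Σ_{g unscreened} λ_g].

A patient served at t ≤ B/c is a backlog patient with wait t; later,
wait(t) = t − (c·t − B)/λ_eff; if λ_eff < c the queue clears at
t\* = B/(c − λ_eff) and waits are zero afterwards. Windowed means integrate
these piecewise-linear waits weighted by the service rate — exact algebra,
no quadrature. At the defaults the oracle gives 40.6 / 72.4 weeks
(status quo, years 1–5 / year 6) and 2.7 / 0 weeks with screening.

The oracle deliberately ignores all stochastic queueing: residual M/D/c
delay in underloaded cells, the sub-week wait induced by weekly batch
release (~0.5 weeks for a patient arriving to an empty queue), and —
most importantly — variance in the clearance time t\*. The last matters
near criticality: at Se = Sp = 0.25 the screened pathway has
λ_eff = 11.25 against c = 12 (ρ ≈ 0.94), the clearance week has a standard
deviation of tens of weeks, and the simulated year-6 mean wait
(~3.3 weeks) exceeds the fluid value (~1.25 weeks) by about 2 weeks —
the one cell where simulation and oracle sit at the edge of each other's
tolerance, and the one cell where the screening scenario leaves a nonzero
year-6 queue. Agreement on all other experiment cells is well within
max(10 %, 2 weeks).

## Numerical and tie-break conventions

* Service epochs at integer weeks 1, 2, …, ⌊T⌋; arrivals at exactly a
  service epoch are queued before that epoch's release (arrival-first).
* FIFO ties (equal arrival time) break by patient id; generated ids are
  assigned in arrival order.
* Reporting windows are half-open (a, b], so a patient served exactly at a
  window boundary belongs to the earlier window.
* An empty window reports mean 0.0 with served-count 0 as the emptiness
  flag; degenerate inputs (zero arrivals, zero backlog) yield all-zero
  counters exactly.
* Replication seeds derived via `numpy.random.SeedSequence`; all derived
  integer seeds are reduced below 2³¹.

## Experiments

1. Status quo vs screening all of A–C at Se = Sp = 0.95.
2. Se/Sp grid: (0.95, 0.95), (0.90, 0.95), (0.95, 0.90) and symmetric
   0.80/0.50/0.25 — the low symmetric points span the "extremely poor
   device" range discussed for the pathway.
3. Capacity 10/12/14 slots per week with screening on.
4. Demand scale 1.00–1.25 in 5 % steps with screening on (the upper end
   is the largest modelled referral increase).
5. Screening restricted to exactly one of groups A, B, C.

All non-varied fields stay at the defaults (c = 12, B = 228,
Se = Sp = 0.95, scale = 1).

## What the generator does and does not emulate

The synthetic stream reproduces the audit's arrival rates, group mix and
abnormality fractions, and independence of status from arrival time. It
does not emulate seasonality, referral clustering, repeat/monitoring
appointments (patients appear once), patient age, within-group casemix, or
borderline/failed device readings. Passing tests therefore demonstrate the
queueing consequences of the audited rates under these idealisations, not
forecasts for any particular service; the audit itself (195 of 261 cases
had full data) likely undercounts true demand, biasing simulated waits
downward.

## Problem sizes

Default test and example runs use 100–400 replications per cell (standard
errors on windowed mean waits are then a few tenths of a week, far below
the tens-of-weeks effect sizes); the acceptance script and the closed-form
convergence check use the protocol's full 2000 replications. One
replication simulates roughly 4 000–5 000 patient events over 260–312
weeks.

## Known limitations

* A false negative simply leaves the model; clinical consequences and
  re-referral pathways are out of scope.
* The weekly batch-release slot mechanism is one reading of "12 slots per
  week"; spreading slots within the week would shave ~0.4 weeks off means
  in uncongested regimes and is indistinguishable under congestion.
* The fluid oracle is a mean-flow approximation; near ρ = 1 its windowed
  waits are biased low by clearance-time variance (see above).
* Confidence intervals use the normal approximation, adequate at the
  replication counts used.
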