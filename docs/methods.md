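# Methods

`surgesim` is an in-silico counterpart to exercise-based hospital surge
capacity testing: casualties with per-injury treatment deadlines are pushed
through a resource-constrained model of one or more hospitals in simulated
real time, and the outcome is read off as preventable mortality,
complications, load curves and numerically determined capacity.  This note
documents the model, the authored defaults, the numerical choices, and what
the simulation does and does not show.

## Time base and determinism

All times are integer minutes after the incident (t = 0).  The alert reaches
the hospital a configurable `alert_delay_min` (default 5) after the
incident.  Every stochastic element (panel draws, deadline jitter,
spontaneous-evacuation arrivals, optional triage error) is driven by an
explicit seed; a run with equal inputs and seed is bit-reproducible, which
the manifest machinery and tests enforce.  Simultaneous events are ordered
by a fixed phase sequence within each minute (completions, transfer
completions, deaths, arrivals, starts) with casualty-id tie-breaks, so the
event order is total and deterministic.

## Casualty cards

A card holds: an injury panel (body region + AIS 1–6), the standard scores
ISS, NISS (sums of squared worst AIS values, with and without the
distinct-region constraint, 75 if any AIS 6) and coded RTS
(0.9368·GCSc + 0.7326·SBPc + 0.2908·RRc with the standard coding tables,
which are general published tables, not specific to any card set); an
ordered treatment plan; a physiological trajectory; and the
`survivable_if_optimal` flag.

**Deadline semantics.**  A time-critical treatment must be *completed* by
`deadline_min`; starting it is not enough.  This is the conservative reading
of "must be done within a certain time": a casualty whose treatment is in
progress when the deadline passes dies.  Completion exactly at the deadline
survives.  Missing the earlier `complication_deadline_min` (but not the hard
deadline) yields a severe complication instead of death.  We place the
complication deadline at or before the death deadline — the soft limit must
come first to be meaningful.

**Survivability oracle.**  `survivable_if_optimal` is computed at generation
time by the greedy check that running the plan back-to-back from t = 0 with
unlimited resources meets every hard deadline.  Panels that fail it (the
shipped `red_unsalvageable` panel, 6 % of REDs) model injuries no care
system could save; their deaths are never counted as preventable.

**Trajectories.**  Physiology is piecewise-constant in (time, set of
completed treatments): the active snapshot is the last listed breakpoint
with `from_min ≤ t` whose condition is a subset of the completed set; past
the untreated death time with the critical treatment still missing, a
deceased marker (GCS 3, SBP 0, RR 0) is returned.  Generated cards use an
initial snapshot consistent with the card's triage category under the
default sieve plus a stabilised snapshot conditioned on the first
intervention, so acquiring treatments never worsens the returned state.

**Triage.**  The field sieve is configuration, not code: walking → GREEN,
apnoeic → DEAD, RR < 10 or > 29 or SBP < 90 or GCS ≤ 13 → RED, else YELLOW.
These thresholds follow common physiological-sieve practice.  Secondary
triage at the hospital door is perfect by default (`triage_error_rate = 0`);
an error rate can be configured and is applied as category swaps with a
seeded RNG.

## Scenario generation

A template fixes category proportions, per-category panel weights, per-panel
deadline jitter and the transport geography.  Scaling to a target casualty
count uses largest-remainder (Hamilton) apportionment with ties broken
RED > YELLOW > GREEN > DEAD: realized counts differ from exact proportions
by less than one per category, so rescaling a scenario to a local population
preserves its injury mix exactly — which is what makes capacities comparable
across hospitals.  The shipped template (10/30/55/5 % red/yellow/green/dead)
and all panel parameters are authored values chosen for clinical
plausibility; real card sets and real exercise scenarios are proprietary,
and no shipped number claims to reproduce a specific hospital or incident.

Deadline jitter is a uniform integer shift of ±15 min (red panels) applied
jointly to the hard and soft deadline of each timed requirement, clamped so
the treatment remains schedulable relative to its own duration.

## Prehospital model

Ambulances all reach the scene `dispatch_delay_min` after the incident and
then cycle load → transport → unload → return → load.  The default fleet
(5 vehicles, 5 min dispatch, 5 min load, 5 min transport, immediate unload)
puts the first casualty in the ED 15 minutes after the incident and gives
severe arrivals a 15-minute wave period.  Scene triage is instantaneous and
perfect: REDs board before YELLOWs, stretcher trips carry one RED/YELLOW,
sitting trips two GREENs; casualties dead at the scene are never
transported.  A configurable fraction of GREENs (default 0.7) leaves by
spontaneous transport as a seeded Poisson stream (default 0.5/min starting
at minute 10) — a continuous trickle, deliberately unlike the ambulance
waves.

## Hospital engine

The engine is an event-driven simulator over a single canonical rulebook;
a brute-force implementation of the same rulebook that evaluates every
minute (`surgesim.reference`) serves as an independent oracle, and the two
must agree event-for-event (tested on randomized scenarios).

Resources and their rules:

* **Trauma units** (REDs only): step-function mobilization after the alert,
  default (0, 2) (20, 6) (40, 10) (60, 16) for the large hospital — full
  mobilization takes an hour, which is what makes the first ambulance waves
  dangerous.  YELLOW/GREEN ED care uses a separate pool of minor-treatment
  slots and never touches trauma units.
* **Staff**: per-category rosters with separate office / non-office
  profiles; off-duty staff reach the roster maximum 30–60 min after the
  alert, and the office profile dominates the non-office profile pointwise.
  Treatments seize their full staff demand for their full duration.
* **OR**: theatres occupied by planned surgery at the alert are cleared
  `or_clearance_min` (default 30) later.  A casualty whose plan includes ICU
  after surgery may only start surgery if an ICU bed can be committed
  (`or_blocks_on_icu`, default on); the committed bed is held through the
  transfer and converted on ICU admission.  This encodes surgery being
  stopped by intensive-care shortage, and makes late preventable deaths
  attributable to the ICU even though the casualty is physically queued for
  the OR.
* **ICU**: beds plus reserve ventilators that come online
  `icu_reserve_ready_min` (default 60) after the alert.
* **CT**: a finite server; when the scanner is outside the ED
  (`ct_in_ed = false`), the visit ties up the casualty's attending staff and
  the scanner for transport + scan + transport.  We hold the scanner for the
  full round trip — a conservative congestion model.
* **Transport staff**: each inter-station move takes `transfer_time_min`
  (default 5) and one transport-staff token; if none is free a clinical
  staff member (default category: nurse) is seized instead and the move is
  logged as indirect capacity loss.
* **Supplies**: treatments record consumable usage; stock-outs are counted
  by post-hoc replay of the log against configured stock rather than by
  halting treatments (in the exercises that motivated the model, shortages
  were bridged by transfers from other hospitals, so the correct signal is a
  flagged shortage, not a stalled casualty).
* **Wards**: finite but generous by default (never the binding constraint).

Queue discipline at every station: triage category first, then least
deadline slack, then arrival order, then id — deterministic and
work-conserving (a RED never waits while a mobilized unit with sufficient
staff is idle; asserted in tests).

Deaths: at every minute, any admitted casualty whose earliest uncompleted
hard deadline has arrived dies, releasing everything it holds.  The death is
attributed to the station where the casualty was waiting or being treated,
refined to ICU when the last start attempt was blocked by the ICU-bed gate.
A casualty arriving after its deadline has already lapsed dies on arrival
(death in transit).

## Outcomes and capacity

A death is **preventable** iff the casualty was survivable under optimal
care.  Since survivability is defined by a feasible schedule from the moment
of injury, every death of a survivable casualty reflects delay imposed by
the system — scene waiting, transport, queueing, or blocked resources.
Complications are scored post-hoc from completion times against soft
deadlines (death dominates: a casualty counted as dead is not also counted
as complicated).  Limiting factors are attributed per phase window (defaults
0–2 h, 2–8 h, 8 h+; configurable) as the station with the most preventable
deaths, with queue-wait pressure breaking ties.

**Capacity** of a component = the largest n in the search range such that
the scenario scaled to n produces zero preventable deaths attributed to that
component in every replicate.  The search is monotone bisection plus a ±2
verification sweep; a detected non-monotone boundary (possible because panel
draws change with n) triggers a warning and an exhaustive linear sweep, in
which case capacity is the largest n with all loads up to n passing.  If
even the lower search bound fails, `n_lo − 1` is returned.  Stochastic
configurations report capacity as "zero preventable deaths in all R
replicates" with R stated (a single physical exercise corresponds to R = 1).

## Regional coordination

Hospitals report free trauma units, queued REDs, free OR and ICU.  The
inflow signal is hysteretic: while accepting, a hospital closes when
predicted arrivals within the lookahead exceed free units plus units
freeing in that window (the stop comes *before* overload); while closed, it
reopens when free units reach the reopen threshold.  The dispatcher observes
hospital state with a reporting latency (default 5 min, minimum 1 — which
also guarantees causality in the co-simulation: hospital simulations always
trail dispatch decisions).  The forecast uses the dispatcher's own en-route
bookkeeping — a perfect short-horizon forecast; forecast noise is out of
scope.  When every hospital is closed, the casualty goes to the hospital
with the greatest predicted slack: holding casualties at the scene would
conflate scene and hospital capacity.  Policy comparisons use common random
numbers (identical scenario, fleet and seeds), so differences are purely the
distribution rule.

## Shipped default conditions

The default overload experiment is 240 casualties (24 RED) against the
large-hospital configuration.  The numbers are authored to sit in the regime
the method is designed to expose, and reproduce the canonical qualitative
sequence across seeds: preventable deaths first appear at the ED during the
arrival waves (teams still mobilizing), the OR — 16 theatres against a
casualty mix that is ED- and ICU-bound — is never fully occupied, and from
the mid-phase onward the ICU (4 beds + 1 reserve ventilator against roughly
15 ICU-bound survivors) is the terminal limiting factor, also via the
surgery gate.  The per-component capacity ranking that results (ICU =
overall < ED < OR) is a property of these authored conditions, not a claim
about any real hospital.

## What passing tests do and do not show

The generator emulates the *structure* of exercise casualty data — category
mix, deadline-bearing treatment plans, score consistency, survivability
flags — not the clinical joint distribution of real injuries: panels are
few, physiology is coarse (three-breakpoint trajectories), service times are
deterministic, and deadlines are panel constants with uniform jitter.
Conclusions about the *mechanics* of surge capacity (wave-driven ED load,
phase ordering of limiting factors, the value of predictive distribution)
transfer; absolute capacity numbers do not, and should be recomputed with a
hospital's own configuration and a locally validated casualty mix.  Further
known limitations: no blood-bank logistics beyond a consumable counter, no
named-staff scheduling or fatigue, no helicopter or secondary-transfer
transport, no burn/hazmat scenario types, and scene organisation is reduced
to instantaneous perfect triage with a finite shuttle fleet.
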