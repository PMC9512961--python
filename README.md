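# surgesim

Discrete-event simulation of **hospital surge capacity** in mass-casualty
incidents (MCI).

When an incident floods a region with casualties, the question that decides
lives is concrete: *how many severely injured patients can this hospital
handle, right now, without preventable deaths?*  Physical exercises that
answer it — simulated casualty cards processed through a real hospital in
real time, with every treatment consuming real staff, rooms, material and
minutes — are accurate but expensive, and their numeric results are usually
kept confidential.  `surgesim` re-creates that test in silico for
preparedness planners, disaster-medicine researchers and operations analysts:
synthetic casualties with time-critical treatment deadlines flow from an
incident scene through ambulance shuttles into ED, CT, OR, ICU and ward
stages with finite, time-mobilized resources, and the simulator counts
preventable deaths and determines, per hospital component and response
phase, the maximum casualty load manageable without preventable mortality.

## The model

* **Casualty cards.**  Each casualty carries an injury panel with AIS
  severities (scored as ISS, NISS and coded RTS), a physiological trajectory
  that is piecewise-constant in time and improves with completed treatments,
  and an ordered plan of treatments.  A treatment binds a station (ED / CT /
  OR / ICU / WARD), a service time, staff and consumable demands, and —
  where time-critical — a hard deadline: the treatment must be *completed*
  within `deadline_min` minutes of the incident to avert death, and within an
  earlier soft deadline to avert a severe complication.
* **Preventable death.**  A casualty who would have survived optimal
  treatment (`survivable_if_optimal`, checked by a greedy scheduling oracle
  at generation time) but whose deadline lapses while waiting — for an
  ambulance, in a queue, or blocked by a full downstream resource — is a
  preventable death, attributed to the station where the deadline lapsed.
* **The hospital.**  Major-incident trauma units (room + equipment +
  minimal qualified team) mobilize along a step curve after the alert;
  YELLOW/GREEN casualties run in a separate low-resource line.  Operating
  theatres occupied by planned surgery are cleared a fixed time after the
  alert.  Surgery for casualties needing post-operative intensive care is
  gated on an ICU bed being available.  CT outside the ED ties up the trauma
  team for the transport round trip.  Inter-station moves consume transport
  staff, falling back to clinical staff when none are free.
* **The scene.**  A finite ambulance fleet shuttles casualties in (REDs
  first), which imprints the characteristic *wave* structure on severe
  arrivals — bursts separated by the round-trip time — while walking wounded
  arrive in a continuous spontaneous stream.
* **Surge capacity.**  For a scenario template whose category mix is held
  fixed (largest-remainder apportionment), the capacity of a component is
  the largest total casualty count whose simulation produces zero
  preventable deaths attributed to that component — found by monotone
  bisection with a verification sweep, falling back to an exhaustive sweep
  if the boundary is not monotone.
* **Regional coordination.**  A "one step ahead" layer closes a hospital's
  inflow *before* predicted arrivals exceed free-plus-freeing trauma units
  and reopens it at a threshold, and distributes REDs across hospitals
  (all-to-centre, round-robin, or predictive lookahead) in a closed-loop
  co-simulation of scene and hospitals.

The event-driven engine is paired with an independent brute-force simulator
(`surgesim.reference`) that walks every single minute; the two must produce
byte-identical event logs, and the test suite holds them to that.

## Worked example

```python
import surgesim as ss
from surgesim.outcome import determine_capacity

template = ss.default_template()     # 10% red / 30% yellow / 55% green / 5% dead
fleet    = ss.default_fleet()        # 5 ambulances; first arrival at minute 15
hospital = ss.large_hospital()       # 16 trauma teams, 16 theatres, 4+1 ICU beds

scenario = ss.generate_scenario(template, 240, seed=1)   # deliberate overload
stream   = ss.simulate_evacuation(scenario, fleet, seed=1)
log      = ss.run(hospital, stream, scenario.bank(), seed=1, horizon_min=1440)
report   = ss.score_outcomes(log, scenario.bank())

print("admitted:", report.n_admitted)
print("preventable deaths:", report.n_preventable)
for d in report.preventable_deaths[:3]:
    print(f"  {d.casualty_id}: {d.station}, deadline {d.deadline_min} min, died {d.t_min} min")
print("limiting factors:", list(report.limiting_factor_sequence))

cap = determine_capacity(hospital, template, fleet, component="overall",
                         search=(5, 260), seeds=(1,))
print("overall capacity:", cap.capacity)
```

prints

```
admitted: 228
preventable deaths: 9
  c0023: ED, deadline 63 min, died 75 min
  c0024: ED, deadline 71 min, died 75 min
  c0022: ED, deadline 94 min, died 94 min
limiting factors: [('0-2h', 'ED'), ('2-8h', 'ICU'), ('8h+', 'none')]
overall capacity: 83
```

Reading: 228 of 240 casualties reach the hospital (12 were dead at the
scene).  The first preventable deaths are severely injured casualties of the
early ambulance waves whose resuscitation deadlines lapse while trauma teams
are still mobilizing; hours later the ICU fills, surgery for ICU-bound
casualties is blocked, and intensive care becomes the terminal limiting
factor.  Under this scenario mix the hospital could have absorbed up to 83
casualties without any preventable death; at 240 it is deliberately
overloaded to expose the limiting-factor sequence.

The same pipeline is scriptable from the shell:

```sh
surgesim gen --n 240 --seed 1 --out out/scen
surgesim run --hospital large-hospital --scenario out/scen/scenario.json \
             --seed 1 --out out/run1
surgesim report --run-dir out/run1
surgesim capacity --hospital large-hospital --seed 1 --n-hi 260
```

Every run directory contains a manifest (config hashes + seed); identical
manifests reproduce byte-identical outputs.

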