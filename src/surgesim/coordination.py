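"""Regional "one step ahead" coordination.

The regional layer distributes severely injured casualties across hospitals
before — not after — any one hospital's trauma capacity is exceeded.  Each
hospital reports its status (free trauma units, queued REDs, free OR/ICU);
the dispatcher predicts near-term arrivals and closes a hospital's inflow
when predicted load exceeds free plus soon-freeing units, reopening it once
enough units are free again.  Three distribution policies are provided: the
historical regional plan that sends every RED to the designated trauma
centre, naive round-robin, and the predictive lookahead policy.

The regional run is a closed-loop co-simulation: ambulance-loading decisions
at the scene query the hospital simulations (with a configurable reporting
latency), and the chosen destinations feed arrivals back into those same
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .casualty import TriageCategory
from .engine import EventLog, HospitalConfig, HospitalSim
from .outcome import OutcomeReport, score_outcomes
from .prehospital import AmbulanceFleet, ArrivalStream, simulate_evacuation
from .scenario import Scenario

__all__ = [
    "StatusReport",
    "DistributionPolicy",
    "inflow_signal",
    "distribute",
    "run_region",
    "RegionResult",
]


class StatusReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_min: int
    hospital_id: int
    free_trauma_units: int = Field(ge=0)
    queued_red: int = Field(ge=0)
    free_or: int
    free_icu: int
    accepting: bool = True


class DistributionPolicy(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["all-red-to-centre", "round-robin", "predictive-lookahead"]
    centre: int = 0
    lookahead_min: int = Field(default=30, ge=0)
    reopen_threshold: int = Field(default=1, ge=0)
    report_latency_min: int = Field(default=5, ge=0)


def inflow_signal(
    report: StatusReport,
    predicted_arrivals: int,
    freeing_within_lookahead: int = 0,
    reopen_threshold: int = 1,
    currently_accepting: bool = True,
) -> bool:
    """Stop/reopen decision for one hospital.

    While accepting, the inflow closes as soon as predicted arrivals within
    the lookahead exceed free units plus units freeing within that window —
    the stop comes *before* the overload.  While closed, the inflow reopens
    once the free-unit count reaches the reopen threshold."""
    if currently_accepting:
        return predicted_arrivals <= report.free_trauma_units + freeing_within_lookahead
    return report.free_trauma_units >= reopen_threshold


def distribute(
    requests: Sequence[tuple[str, TriageCategory]],
    hospitals: Sequence[StatusReport],
    policy: DistributionPolicy,
) -> list[int]:
    """Open-loop assignment of casualties to hospitals, one id per request.

    ``all-red-to-centre`` sends every RED to the designated centre regardless
    of signals (the historical regional plan); others round-robin.
    ``round-robin`` cycles all casualties.  ``predictive-lookahead`` sends
    each RED to the accepting hospital with the most free trauma units
    (falling back to the least-loaded hospital when none accepts — casualties
    cannot be held at the scene indefinitely); others round-robin.
    """
    if not hospitals:
        raise ValueError("at least one hospital required")
    n = len(hospitals)
    free = [h.free_trauma_units for h in hospitals]
    accepting = [h.accepting for h in hospitals]
    out: list[int] = []
    rr = 0
    for cid, cat in requests:
        if policy.kind == "round-robin":
            out.append(rr % n)
            rr += 1
            continue
        if cat is not TriageCategory.RED:
            out.append(rr % n)
            rr += 1
            continue
        if policy.kind == "all-red-to-centre":
            if not 0 <= policy.centre < n:
                raise ValueError(f"unknown centre hospital {policy.centre}")
            out.append(policy.centre)
            continue
        if policy.kind == "predictive-lookahead":
            candidates = [i for i in range(n) if accepting[i]] or list(range(n))
            best = max(candidates, key=lambda i: (free[i], -i))
            free[best] -= 1  # account for our own assignment
            out.append(best)
            continue
        raise ValueError(f"unknown policy kind {policy.kind!r}")  # pragma: no cover
    return out


# ---------------------------------------------------------------------------
# Closed-loop regional run
# ---------------------------------------------------------------------------

@dataclass
class RegionResult:
    stream: ArrivalStream
    logs: list[EventLog]
    reports: list[OutcomeReport]
    status_log: list[StatusReport]
    scene_deaths: list[dict]

    @property
    def total_preventable(self) -> int:
        hospital = sum(r.n_preventable for r in self.reports)
        scene = sum(1 for d in self.scene_deaths if d["preventable"])
        return hospital + scene


def run_region(
    scenario: Scenario,
    fleet: AmbulanceFleet,
    hospitals: Sequence[HospitalConfig],
    policy: DistributionPolicy,
    seed: Optional[int] = None,
    profile: str = "office",
    horizon_min: int = 1440,
) -> RegionResult:
    """Co-simulate scene evacuation and every hospital under a policy.

    At each ambulance load completion the dispatcher observes hospital state
    as of ``t - report_latency_min`` (at least one minute old, so hospital
    simulations never run past an arrival they have not yet been told about),
    updates each hospital's accept/stop signal with hysteresis, and routes
    the vehicle.  Common random numbers: the same scenario and seed yield
    identical ambulance cycles and spontaneous streams across policies, so
    policy comparisons are paired.
    """
    if len(fleet.transport_time_min) != len(hospitals):
        raise ValueError("fleet transport times must match number of hospitals")
    seed = scenario.seed if seed is None else seed
    bank = scenario.bank()
    sims = [HospitalSim(cfg, bank, profile=profile, seed=seed) for cfg in hospitals]
    accepting = [True] * len(hospitals)
    en_route: list[list[tuple[int, str]]] = [[] for _ in hospitals]  # (arrival_min, cid)
    status_log: list[StatusReport] = []
    rr_counter = [0]

    def make_report(i: int, t_obs: int) -> StatusReport:
        s = sims[i].status(t_obs)
        return StatusReport(
            t_min=t_obs, hospital_id=i,
            free_trauma_units=max(0, s["free_trauma_units"]),
            queued_red=s["queued_red"], free_or=s["free_or"], free_icu=s["free_icu"],
            accepting=accepting[i],
        )

    def destination(t_load_end: int, cid: str) -> int:
        cat = bank[cid].true_category
        t_obs = max(0, t_load_end - max(1, policy.report_latency_min))
        for sim in sims:
            sim.advance_to(t_obs)
        n = len(hospitals)
        if cat is not TriageCategory.RED or policy.kind == "round-robin":
            dest = rr_counter[0] % n
            rr_counter[0] += 1
            return dest
        if policy.kind == "all-red-to-centre":
            return policy.centre
        # predictive-lookahead
        reports = []
        slack = []
        for i in range(n):
            rep = make_report(i, t_obs)
            pending = sum(1 for (ta, _) in en_route[i] if ta > t_obs)
            within = sum(1 for (ta, _) in en_route[i]
                         if t_obs < ta <= t_obs + policy.lookahead_min)
            freeing = sims[i].freeing_within(t_obs, policy.lookahead_min)
            accepting[i] = inflow_signal(
                rep, within + 1, freeing, policy.reopen_threshold, accepting[i]
            )
            rep = rep.model_copy(update={"accepting": accepting[i]})
            reports.append(rep)
            slack.append(rep.free_trauma_units + freeing - pending)
            status_log.append(rep)
        candidates = [i for i in range(n) if accepting[i]]
        if candidates:
            return max(candidates, key=lambda i: (slack[i], -i))
        # Everyone closed: least predicted overload (cannot hold at scene).
        return max(range(n), key=lambda i: (slack[i], -i))

    def routed_destination(t: int, cid: str) -> int:
        dest = destination(t, cid)
        if bank[cid].true_category is TriageCategory.RED:
            # Only REDs matter for trauma-unit load prediction.
            en_route[dest].append((t + fleet.transport_time_min[dest], cid))
        return dest

    def feed(a) -> None:
        # Reporting latency keeps every sim at least one minute behind the
        # dispatch decision, so arrivals are always in the sim's future.
        sims[a.hospital_id].admit(a.casualty_id, a.arrival_min)

    stream = simulate_evacuation(
        scenario, fleet, destination=routed_destination, seed=seed, on_arrival=feed
    )
    for sim in sims:
        sim.run_to_completion(horizon_min)

    transported = {a.casualty_id for a in stream.arrivals}
    scene_deaths = []
    for c in scenario.casualties:
        if c.id in transported or c.true_category is TriageCategory.DEAD:
            continue
        deadlines = [r.deadline_min for r in c.time_critical_requirements]
        if deadlines and min(deadlines) <= horizon_min:
            scene_deaths.append({
                "casualty_id": c.id, "t_min": min(deadlines), "station": "SCENE",
                "preventable": c.survivable_if_optimal,
            })

    logs = [sim.log for sim in sims]
    reports = [score_outcomes(log, bank) for log in logs]
    return RegionResult(
        stream=stream, logs=logs, reports=reports,
        status_log=status_log, scene_deaths=scene_deaths,
    )
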