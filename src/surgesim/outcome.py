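"""Endpoints of a surge-capacity test.

Turns an event log into the quantities the method is designed to measure:
preventable deaths with cause attribution (a death is preventable when the
casualty would have survived optimal treatment and the missed deadline
elapsed while the casualty was waiting for transport, a queue, or a blocked
resource), complications from missed soft deadlines, per-station load curves,
the phase-by-phase sequence of limiting factors, and — by repeated
simulation — the surge capacity itself: the largest casualty load a hospital
component handles without preventable mortality.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .casualty import Casualty, Station
from .engine import EventLog, HospitalConfig, mobilized, run
from .prehospital import AmbulanceFleet, simulate_evacuation
from .scenario import ScenarioTemplate, generate_scenario

__all__ = [
    "DeathRecord",
    "ComplicationRecord",
    "OutcomeReport",
    "LoadCurve",
    "score_outcomes",
    "load_curves",
    "determine_capacity",
    "CapacityResult",
    "DEFAULT_PHASE_WINDOWS",
]

#: Phase windows for limiting-factor attribution (minutes post-incident);
#: anchored to the typical response chronology: ED in the first hours, OR in
#: the middle phase, ICU from then on.  Configurable per call.
DEFAULT_PHASE_WINDOWS: tuple[tuple[int, Optional[int], str], ...] = (
    (0, 120, "0-2h"),
    (120, 480, "2-8h"),
    (480, None, "8h+"),
)

_DEATH_RE = re.compile(r"req=(\S+) deadline=(\d+) blocked_on=(\S+) wait=(\d+)")


class DeathRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    casualty_id: str
    t_min: int
    station: str
    requirement: str
    deadline_min: int
    wait_min: int
    blocked_on: str
    preventable: bool


class ComplicationRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    casualty_id: str
    requirement: str
    station: str
    soft_deadline_min: int
    completed_min: Optional[int]
    preventable: bool


class OutcomeReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_admitted: int
    n_diverted: int
    preventable_deaths: tuple[DeathRecord, ...]
    non_preventable_deaths: tuple[DeathRecord, ...]
    complications: tuple[ComplicationRecord, ...]
    limiting_factor_sequence: tuple[tuple[str, str], ...]  # (phase label, station)

    @property
    def n_preventable(self) -> int:
        return len(self.preventable_deaths)


def _phase_of(t: int, windows) -> str:
    for lo, hi, label in windows:
        if t >= lo and (hi is None or t < hi):
            return label
    return windows[-1][2]


def score_outcomes(
    log: EventLog,
    bank: dict[str, Casualty],
    phase_windows=DEFAULT_PHASE_WINDOWS,
) -> OutcomeReport:
    """Classify every death in the log and attribute limiting factors.

    A death is preventable iff the casualty was survivable under optimal
    treatment: by construction of the casualty bank a feasible treatment
    schedule existed from the moment of injury, so any death of such a
    casualty reflects delay imposed by transport, queueing or blocked
    resources rather than the injury itself.  The death event's station is
    where the deadline lapsed (refined to ICU when the surgery gate on ICU
    beds was the blocker).
    """
    deaths_p: list[DeathRecord] = []
    deaths_np: list[DeathRecord] = []
    completed: dict[tuple[str, str], int] = {}
    died: set[str] = set()
    n_admitted = n_diverted = 0
    max_t = 0
    for e in log.events:
        max_t = max(max_t, e.t)
        if e.kind == "arrive":
            n_admitted += 1
        elif e.kind == "divert":
            n_diverted += 1
        elif e.kind == "treatment_end":
            rid = e.detail.split("req=", 1)[1].split()[0]
            completed[(e.subject, rid)] = e.t
        elif e.kind == "death":
            if e.subject not in bank:
                raise KeyError(f"death event for unknown casualty {e.subject!r}")
            m = _DEATH_RE.match(e.detail)
            if not m:
                raise ValueError(f"malformed death detail {e.detail!r}")
            died.add(e.subject)
            rec = DeathRecord(
                casualty_id=e.subject,
                t_min=e.t,
                station=e.station,
                requirement=m.group(1),
                deadline_min=int(m.group(2)),
                wait_min=int(m.group(4)),
                blocked_on=m.group(3),
                preventable=bank[e.subject].survivable_if_optimal,
            )
            (deaths_p if rec.preventable else deaths_np).append(rec)

    # Complications: soft deadline missed but the casualty survived it.
    compl: list[ComplicationRecord] = []
    seen = {e.subject for e in log.events if e.kind == "arrive"}
    for cid in sorted(seen):
        c = bank[cid]
        for req in c.requirements:
            cd = req.complication_deadline_min
            if cd is None:
                continue
            done_t = completed.get((cid, req.id))
            if done_t is not None and done_t <= cd:
                continue
            if done_t is None:
                if cid in died or max_t < cd:
                    continue  # death dominates / deadline not yet reached
            compl.append(ComplicationRecord(
                casualty_id=cid, requirement=req.id, station=req.station.value,
                soft_deadline_min=cd, completed_min=done_t,
                preventable=c.survivable_if_optimal,
            ))

    # Limiting factor per phase: station with the most preventable deaths;
    # waiting pressure (queue minutes from queue_exit records) breaks ties.
    pressure: dict[str, dict[str, float]] = {}
    labels = [w[2] for w in phase_windows]
    for rec in deaths_p:
        ph = _phase_of(rec.t_min, phase_windows)
        pressure.setdefault(ph, {}).setdefault(rec.station, 0.0)
        pressure[ph][rec.station] += 1000.0  # deaths dominate waiting pressure
    for e in log.events:
        if e.kind == "queue_exit" and "wait=" in e.detail:
            w = int(e.detail.split("wait=", 1)[1])
            if w > 0:
                ph = _phase_of(e.t, phase_windows)
                pressure.setdefault(ph, {}).setdefault(e.station, 0.0)
                pressure[ph][e.station] += w
    sequence = []
    for label in labels:
        by_station = pressure.get(label, {})
        if by_station:
            station = max(sorted(by_station), key=lambda s: by_station[s])
            sequence.append((label, station))
        else:
            sequence.append((label, "none"))

    return OutcomeReport(
        n_admitted=n_admitted,
        n_diverted=n_diverted,
        preventable_deaths=tuple(deaths_p),
        non_preventable_deaths=tuple(deaths_np),
        complications=tuple(compl),
        limiting_factor_sequence=tuple(sequence),
    )


# ---------------------------------------------------------------------------
# Load curves
# ---------------------------------------------------------------------------

@dataclass
class LoadCurve:
    """Tidy per-bin station load: columns t_bin, station, category, metric,
    value.  Metrics: in_action, waiting (sampled at bin start), at_disposal
    (trauma units only), arrivals (count per bin), preventable_deaths_cum."""

    frame: pd.DataFrame
    bin_min: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_curves(
    log: EventLog,
    bin_min: int,
    hospital: Optional[HospitalConfig] = None,
    profile: str = "office",
    bank: Optional[dict[str, Casualty]] = None,
    horizon_min: Optional[int] = None,
) -> LoadCurve:
    if bin_min < 1:
        raise ValueError("bin_min must be >= 1")
    events = log.events
    horizon = horizon_min if horizon_min is not None else (max((e.t for e in events), default=0) + 1)
    n = horizon + 1
    stations = [s.value for s in Station]
    category: dict[str, str] = {}
    in_action = {s: [0] * n for s in stations}
    red_units = [0] * n  # trauma units in action (RED casualties in ED care)
    waiting = {s: [0] * n for s in stations}
    deaths_cum = [0] * n
    arrivals_by_cat: dict[str, list[int]] = {}

    def mark(series, t0, t1):
        # occupancy over [t0, t1)
        for t in range(t0, min(t1, n)):
            series[t] += 1

    def close_treat(cid: str, station: str, t1: int) -> None:
        t0 = open_treat.pop((cid, station), None)
        if t0 is None:
            return
        mark(in_action[station], t0, t1)
        if station == Station.ED.value and category.get(cid) == "red":
            mark(red_units, t0, t1)

    open_treat: dict[tuple[str, str], int] = {}
    open_wait: dict[tuple[str, str], int] = {}
    for e in events:
        if e.kind == "triage2":
            category[e.subject] = e.detail.split("category=", 1)[1]
        elif e.kind == "queue_enter":
            open_wait[(e.subject, e.station)] = e.t
        elif e.kind == "queue_exit":
            t0 = open_wait.pop((e.subject, e.station), None)
            if t0 is not None:
                mark(waiting[e.station], t0, e.t)
        elif e.kind == "treatment_start":
            open_treat[(e.subject, e.station)] = e.t
        elif e.kind == "treatment_end":
            close_treat(e.subject, e.station, e.t)
        elif e.kind == "death":
            t0 = open_wait.pop((e.subject, e.station), None)
            if t0 is not None:
                mark(waiting[e.station], t0, e.t)
            close_treat(e.subject, e.station, e.t)
            if bank is not None and bank.get(e.subject) is not None and bank[e.subject].survivable_if_optimal:
                for t in range(e.t, n):
                    deaths_cum[t] += 1
    # Still-open intervals run to the horizon (occupants at horizon).
    for (cid, st) in list(open_treat):
        close_treat(cid, st, n)
    for (cid, st), t0 in open_wait.items():
        mark(waiting[st], t0, n)
    for e in events:
        if e.kind == "arrive":
            cat = category.get(e.subject, "unknown")
            arrivals_by_cat.setdefault(cat, [0] * n)[e.t] += 1

    rows = []
    bins = range(0, n, bin_min)
    for tb in bins:
        for st in stations:
            rows.append((tb, st, "all", "in_action", in_action[st][tb]))
            rows.append((tb, st, "all", "waiting", waiting[st][tb]))
        if hospital is not None:
            mob = mobilized(hospital, "trauma_units", tb, profile)
            rows.append((tb, "ED", "red", "in_action", red_units[tb]))
            rows.append((tb, "ED", "red", "at_disposal", mob - red_units[tb]))
        rows.append((tb, "", "all", "preventable_deaths_cum", deaths_cum[tb]))
        for cat in sorted(arrivals_by_cat):
            rows.append((tb, "", cat, "arrivals", sum(arrivals_by_cat[cat][tb:tb + bin_min])))
    frame = pd.DataFrame(rows, columns=["t_bin", "station", "category", "metric", "value"])
    return LoadCurve(frame=frame, bin_min=bin_min)


# ---------------------------------------------------------------------------
# Capacity determination
# ---------------------------------------------------------------------------

@dataclass
class CapacityResult:
    capacity: int
    component: str
    method: str          # "bisection" | "linear-sweep"
    replicates: int
    n_evaluated: int = 0
    evaluations: dict = field(default_factory=dict)


def _component_deaths(report: OutcomeReport, component: str) -> int:
    if component == "overall":
        return report.n_preventable
    return sum(1 for d in report.preventable_deaths if d.station == component)


def determine_capacity(
    hospital: HospitalConfig,
    template: ScenarioTemplate,
    fleet: AmbulanceFleet,
    component: str = "overall",
    search: tuple[int, int] = (1, 100),
    seeds: Sequence[int] = (1,),
    profile: str = "office",
    horizon_min: int = 1440,
) -> CapacityResult:
    """Largest total casualty count in ``search`` for which the scaled
    scenario produces zero preventable deaths attributed to ``component``
    across every replicate seed.

    Monotone bisection with a +/-2 verification sweep; if the sweep reveals a
    non-monotone boundary, falls back to an exhaustive linear sweep (capacity
    is then the largest n such that every load up to n passes).  If even the
    lower search bound fails, returns ``n_lo - 1``.
    """
    n_lo, n_hi = search
    if not n_lo < n_hi:
        raise ValueError("search requires n_lo < n_hi")
    cache: dict[int, bool] = {}

    def passes(n: int) -> bool:
        if n not in cache:
            ok = True
            for seed in seeds:
                scenario = generate_scenario(template, n, seed)
                stream = simulate_evacuation(scenario, fleet, destination=0, seed=seed)
                log = run(hospital, stream, scenario.bank(), seed=seed,
                          profile=profile, horizon_min=horizon_min)
                report = score_outcomes(log, scenario.bank())
                if _component_deaths(report, component) > 0:
                    ok = False
                    break
            cache[n] = ok
        return cache[n]

    def linear() -> int:
        cap = n_lo - 1
        for n in range(n_lo, n_hi + 1):
            if not passes(n):
                break
            cap = n
        return cap

    if not passes(n_lo):
        return CapacityResult(n_lo - 1, component, "bisection", len(seeds), len(cache), dict(cache))
    if passes(n_hi):
        cap = n_hi
    else:
        lo, hi = n_lo, n_hi  # passes(lo), fails(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if passes(mid):
                lo = mid
            else:
                hi = mid
        cap = lo
    # Verification sweep +/-2 around the answer.
    monotone = True
    for n in range(max(n_lo, cap - 2), min(n_hi, cap + 2) + 1):
        if (n <= cap) != passes(n):
            monotone = False
            break
    if not monotone:
        warnings.warn(
            f"capacity boundary for {component!r} is not monotone near n={cap}; "
            "falling back to exhaustive linear sweep",
            stacklevel=2,
        )
        cap = linear()
        return CapacityResult(cap, component, "linear-sweep", len(seeds), len(cache), dict(cache))
    return CapacityResult(cap, component, "bisection", len(seeds), len(cache), dict(cache))
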