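"""Scene-to-hospital evacuation.

A finite ambulance fleet shuttles between the scene and the hospitals:
dispatch delay, loading, transport, unloading, return, re-loading.  With few
vehicles this cycle imprints the characteristic "wave" structure on severely
injured arrivals — bursts separated by the round-trip time — while walking
wounded leave the scene in a continuous spontaneous stream that does not
depend on ambulances.  Scene triage loads REDs before YELLOWs; casualties
dead at the scene are never transported.
"""

from __future__ import annotations

from dataclasses import dataclass
import heapq
from typing import Callable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .casualty import TriageCategory
from .scenario import Scenario

__all__ = [
    "AmbulanceFleet",
    "Arrival",
    "ArrivalStream",
    "Wave",
    "simulate_evacuation",
    "wave_decomposition",
]


class AmbulanceFleet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_ambulances: int = Field(default=4, ge=0)
    stretcher_capacity: int = Field(default=1, ge=1)   # RED/YELLOW per trip
    sitting_capacity: int = Field(default=2, ge=1)     # GREEN per trip
    dispatch_delay_min: int = Field(default=5, ge=0)   # first vehicle on scene
    load_min: int = Field(default=5, ge=0)
    unload_min: int = Field(default=0, ge=0)
    transport_time_min: tuple[int, ...] = (5,)         # per hospital
    # Spontaneous evacuation of walking wounded (not ambulance-dependent).
    green_spontaneous_fraction: float = Field(default=0.7, ge=0.0, le=1.0)
    spontaneous_rate_per_min: float = Field(default=0.5, gt=0.0)
    spontaneous_start_min: int = Field(default=10, ge=0)


@dataclass(frozen=True, order=True)
class Arrival:
    arrival_min: int
    casualty_id: str
    hospital_id: int
    mode: str  # "ambulance" | "spontaneous"
    category: TriageCategory


class ArrivalStream(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    arrivals: tuple[Arrival, ...] = ()

    def for_hospital(self, hospital_id: int) -> "ArrivalStream":
        return ArrivalStream(arrivals=tuple(a for a in self.arrivals if a.hospital_id == hospital_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "arrival_min": a.arrival_min,
                    "casualty_id": a.casualty_id,
                    "hospital_id": a.hospital_id,
                    "mode": a.mode,
                    "category": a.category.value,
                }
                for a in self.arrivals
            ],
            columns=["arrival_min", "casualty_id", "hospital_id", "mode", "category"],
        )


def simulate_evacuation(
    scenario: Scenario,
    fleet: AmbulanceFleet,
    destination: int | Callable[[int, str], int] = 0,
    seed: Optional[int] = None,
    on_arrival: Optional[Callable[[Arrival], None]] = None,
) -> ArrivalStream:
    """Shuttle-cycle evacuation of a scenario's casualties.

    ``destination`` is either a fixed hospital index or a callable
    ``(load_complete_min, casualty_id) -> hospital index`` evaluated when an
    ambulance finishes loading (this is the hook the regional coordination
    layer uses).  ``on_arrival`` is invoked for every scheduled arrival the
    moment it becomes known — spontaneous departures up front, ambulance
    arrivals at load time in chronological dispatch order — so a co-simulated
    hospital can be fed incrementally.  Spontaneous GREEN departures are a
    seeded Poisson stream; ``seed`` defaults to the scenario's own seed.
    Deterministic given inputs.
    """
    n_hosp = len(fleet.transport_time_min)
    if callable(destination):
        dest_fn = destination
    else:
        if not 0 <= destination < n_hosp:
            raise ValueError(f"unknown hospital index {destination}")
        dest_fn = lambda t, cid: destination
    rng = np.random.default_rng([scenario.seed if seed is None else seed, 0x5E])

    by_cat = scenario.by_category
    greens = by_cat[TriageCategory.GREEN]
    n_spont = int(round(fleet.green_spontaneous_fraction * len(greens)))
    spont_idx = set(rng.choice(len(greens), size=n_spont, replace=False).tolist()) if n_spont else set()
    spontaneous = [greens[i] for i in sorted(spont_idx)]
    amb_greens = [g for i, g in enumerate(greens) if i not in spont_idx]

    arrivals: list[Arrival] = []

    # Spontaneous stream: Poisson process, not ambulance-dependent; walking
    # wounded head for the nearest hospital.
    nearest = int(np.argmin(fleet.transport_time_min))
    t = float(fleet.spontaneous_start_min)
    for c in spontaneous:
        t += rng.exponential(1.0 / fleet.spontaneous_rate_per_min)
        a = Arrival(int(round(t)), c.id, nearest, "spontaneous", TriageCategory.GREEN)
        arrivals.append(a)
        if on_arrival is not None:
            on_arrival(a)

    # Ambulance shuttle: scene queue in triage priority order.
    queue = list(by_cat[TriageCategory.RED]) + list(by_cat[TriageCategory.YELLOW]) + amb_greens
    if fleet.n_ambulances > 0 and queue:
        heap = [(fleet.dispatch_delay_min, i) for i in range(fleet.n_ambulances)]
        heapq.heapify(heap)
        pos = 0
        while pos < len(queue):
            ready, amb = heapq.heappop(heap)
            load_end = ready + fleet.load_min
            first = queue[pos]
            if first.true_category is TriageCategory.GREEN:
                trip = queue[pos : pos + fleet.sitting_capacity]
            else:
                trip = queue[pos : pos + fleet.stretcher_capacity]
                trip = [c for c in trip if c.true_category is first.true_category] or [first]
            pos += len(trip)
            dest = dest_fn(load_end, first.id)
            if not 0 <= dest < n_hosp:
                raise ValueError(f"destination policy returned unknown hospital {dest}")
            t_arr = load_end + fleet.transport_time_min[dest]
            for c in trip:
                a = Arrival(t_arr, c.id, dest, "ambulance", c.true_category)
                arrivals.append(a)
                if on_arrival is not None:
                    on_arrival(a)
            ready_again = t_arr + fleet.unload_min + fleet.transport_time_min[dest]
            heapq.heappush(heap, (ready_again, amb))

    arrivals.sort(key=lambda a: (a.arrival_min, a.casualty_id))
    return ArrivalStream(arrivals=tuple(arrivals))


@dataclass(frozen=True)
class Wave:
    start_min: int
    end_min: int
    count: int
    mix: dict  # category value -> count


def wave_decomposition(stream: ArrivalStream, gap_min: int) -> list[Wave]:
    """Partition ambulance-borne RED/YELLOW arrivals into maximal runs
    separated by inter-arrival gaps greater than ``gap_min``."""
    pts = sorted(
        (a for a in stream.arrivals
         if a.mode == "ambulance" and a.category in (TriageCategory.RED, TriageCategory.YELLOW)),
        key=lambda a: (a.arrival_min, a.casualty_id),
    )
    waves: list[Wave] = []
    run: list[Arrival] = []
    for a in pts:
        if run and a.arrival_min - run[-1].arrival_min > gap_min:
            waves.append(_close(run))
            run = []
        run.append(a)
    if run:
        waves.append(_close(run))
    return waves


def _close(run: list[Arrival]) -> Wave:
    mix: dict[str, int] = {}
    for a in run:
        mix[a.category.value] = mix.get(a.category.value, 0) + 1
    return Wave(start_min=run[0].arrival_min, end_min=run[-1].arrival_min, count=len(run), mix=mix)
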