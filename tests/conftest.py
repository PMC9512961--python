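"""Shared fixtures: minimal hospitals, deterministic casualty builders, and
an identical-REDs template whose capacity is known in closed form."""

from __future__ import annotations

import pytest

from surgesim import (
    AmbulanceFleet,
    Casualty,
    Geography,
    HospitalConfig,
    Injury,
    InjuryPanel,
    PhysiologySnapshot,
    ScenarioTemplate,
    Station,
    Trajectory,
    TrajectoryBreakpoint,
    TreatmentRequirement,
    TriageCategory,
    default_fleet,
    default_template,
    large_hospital,
    regional_hospital,
)

AMPLE_ROSTER = {
    "doctor": {"office": ((0, 50),), "non-office": ((0, 50),)},
    "nurse": {"office": ((0, 100),), "non-office": ((0, 100),)},
}


@pytest.fixture
def template():
    return default_template()

@pytest.fixture
def fleet():
    return default_fleet()

@pytest.fixture
def big_hospital():
    return large_hospital()

@pytest.fixture
def small_hospital():
    return regional_hospital()


def make_red(
    cid: str,
    deadline: int | None,
    duration: int = 20,
    station: Station = Station.ED,
    extra_reqs: tuple[TreatmentRequirement, ...] = (),
    survivable: bool | None = None,
) -> Casualty:
    """One severely injured casualty with a single timed requirement (plus
    optional follow-on requirements), for hand-traceable queue fixtures."""
    req = TreatmentRequirement(
        id=f"{cid}_treat", station=station, duration_min=duration,
        deadline_min=deadline, staff_demand={"nurse": 1},
    )
    reqs = (req,) + extra_reqs
    snap = PhysiologySnapshot(gcs=12, sbp=80, rr=24, ambulatory=False)
    deadlines = [r.deadline_min for r in reqs if r.deadline_min is not None]
    if survivable is None:
        t = 0
        survivable = True
        for r in reqs:
            t += r.duration_min
            if r.deadline_min is not None and t > r.deadline_min:
                survivable = False
    return Casualty(
        id=cid,
        injuries=(Injury(body_region="thorax", ais=4),),
        requirements=reqs,
        trajectory=Trajectory(
            breakpoints=(TrajectoryBreakpoint(from_min=0, condition=(), snapshot=snap),),
            death_time_untreated_min=min(deadlines) if deadlines else None,
        ),
        survivable_if_optimal=survivable,
        iss=16, niss=16, rts=5.9672,
        true_category=TriageCategory.RED,
    )


def single_unit_hospital(**overrides) -> HospitalConfig:
    """One trauma unit, ample staff, no transfers: a pure single-server queue."""
    kwargs = dict(
        name="single-unit",
        n_trauma_units_max=1,
        trauma_unit_mobilization=((0, 1),),
        n_minor_treatment_slots=2,
        n_or_theatres=1,
        n_icu_beds=1,
        n_ward_beds=10,
        n_ct=1,
        ct_in_ed=True,
        transport_staff=2,
        transfer_time_min=0,
        staff_roster=AMPLE_ROSTER,
        alert_delay_min=5,
    )
    kwargs.update(overrides)
    return HospitalConfig(**kwargs)


def uniform_red_template(deadline: int = 75, duration: int = 20) -> ScenarioTemplate:
    """All-RED template with identical, jitter-free cards.

    With one trauma unit, a single shuttling ambulance (cycle 15 min, first
    arrival minute 15) and service time 20, arrivals at 15, 30, 45, ... are
    served back-to-back finishing at 35, 55, 75, ...: exactly three casualties
    complete by a 75-minute deadline, so the closed-form capacity is 3.
    """
    panel = InjuryPanel(
        id="red_uniform", category=TriageCategory.RED,
        injuries=(Injury(body_region="thorax", ais=4),),
        requirements=(
            TreatmentRequirement(
                id="resus", station=Station.ED, duration_min=duration,
                deadline_min=deadline, staff_demand={"nurse": 1},
            ),
        ),
    )
    return ScenarioTemplate(
        name="uniform-red",
        category_proportions={TriageCategory.RED: 1.0},
        panel_weights={TriageCategory.RED: {"red_uniform": 1.0}},
        geography=Geography(n_hospitals=1, transport_time_min=(5,)),
        panels={"red_uniform": panel},
    )


def single_ambulance_fleet() -> AmbulanceFleet:
    return AmbulanceFleet(
        n_ambulances=1, dispatch_delay_min=5, load_min=5, unload_min=0,
        transport_time_min=(5,), green_spontaneous_fraction=0.0,
    )
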