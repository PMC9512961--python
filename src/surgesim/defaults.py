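"""Shipped default configurations.

All values are repo-authored exercise defaults chosen for clinical
plausibility (real per-hospital capacity figures are not public).  The fleet
default is calibrated so the first ambulance reaches the hospital 15 minutes
after the incident (dispatch 5 + load 5 + transport 5); off-duty staff reach
their maximum 30-60 minutes after the alert.
"""

from __future__ import annotations

from .engine import HospitalConfig
from .prehospital import AmbulanceFleet

__all__ = ["large_hospital", "regional_hospital", "default_fleet", "BUILTIN_HOSPITALS"]


def large_hospital() -> HospitalConfig:
    """University-hospital-scale trauma centre: many trauma units mobilizable,
    generous OR capacity, ICU the scarcest late resource."""
    return HospitalConfig(
        name="large-hospital",
        n_trauma_units_max=16,
        trauma_unit_mobilization=((0, 2), (20, 6), (40, 10), (60, 16)),
        n_minor_treatment_slots=10,
        n_or_theatres=16,
        or_initial_occupied=9,
        or_clearance_min=30,
        n_icu_beds=4,
        icu_reserve_ventilators=1,
        icu_reserve_ready_min=60,
        n_ward_beds=200,
        n_ct=2,
        ct_in_ed=False,
        ct_transport_min=10,
        transport_staff=4,
        transfer_time_min=5,
        staff_roster={
            "doctor": {
                "office": ((0, 8), (30, 18), (60, 26)),
                "non-office": ((0, 4), (30, 12), (60, 26)),
            },
            "nurse": {
                "office": ((0, 16), (30, 32), (60, 48)),
                "non-office": ((0, 9), (30, 24), (60, 48)),
            },
        },
        supplies={"or_disposable_set": 12, "ext_fix_set": 2, "neuro_set": 2},
        alert_delay_min=5,
    )


def regional_hospital() -> HospitalConfig:
    """Smaller regional hospital: fewer trauma units and theatres, minimal ICU."""
    return HospitalConfig(
        name="regional-hospital",
        n_trauma_units_max=4,
        trauma_unit_mobilization=((0, 1), (15, 2), (45, 4)),
        n_minor_treatment_slots=6,
        n_or_theatres=4,
        or_initial_occupied=2,
        or_clearance_min=30,
        n_icu_beds=3,
        icu_reserve_ventilators=1,
        icu_reserve_ready_min=60,
        n_ward_beds=80,
        n_ct=1,
        ct_in_ed=False,
        ct_transport_min=10,
        transport_staff=2,
        transfer_time_min=5,
        staff_roster={
            "doctor": {
                "office": ((0, 3), (30, 6), (60, 10)),
                "non-office": ((0, 2), (30, 5), (60, 10)),
            },
            "nurse": {
                "office": ((0, 8), (30, 14), (60, 20)),
                "non-office": ((0, 5), (30, 10), (60, 20)),
            },
        },
        supplies={"or_disposable_set": 6, "ext_fix_set": 1},
        alert_delay_min=5,
    )


def default_fleet(n_hospitals: int = 1) -> AmbulanceFleet:
    """Default ambulance fleet: first scene arrival at 5 min, 5 min loading,
    5 min transport to each hospital -> first hospital arrival at minute 15."""
    return AmbulanceFleet(
        n_ambulances=5,
        dispatch_delay_min=5,
        load_min=5,
        unload_min=0,
        transport_time_min=tuple([5] * n_hospitals),
    )


BUILTIN_HOSPITALS = {
    "large-hospital": large_hospital,
    "regional-hospital": regional_hospital,
}
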